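# Model 2: SWP = a*exp(b*PLWP)*VPDmax^p + c  (published fit)
form: M2
a: 1.518
b: 4.063
p: -0.233
c: -1.614
rmse_train: 0.205
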