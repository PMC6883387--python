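# Model 1: SWP = a*exp(b*PLWP) + c  (published fit)
form: M1
a: 1.243
b: 4.011
c: -1.616
rmse_train: 0.214
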