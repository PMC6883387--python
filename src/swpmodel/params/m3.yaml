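# Model 3: SWP = a*exp(b*PLWP)*Tmax^p + c  (published fit)
form: M3
a: 20.164
b: 3.890
p: -0.819
c: -1.628
rmse_train: 0.201
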