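# Model 5: SWP = a*exp(b*PLWP)*Tmax^p + d*DOY + c  (published fit)
form: M5
a: 24.789
b: 2.144
p: -0.896
d: -0.00543
c: -0.579
rmse_train: 0.164
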