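# Model 4: SWP = a*exp(b*PLWP)*VPDmax^p + d*DOY + c  (published fit)
form: M4
a: 1.479
b: 2.304
p: -0.318
d: -0.00580
c: -0.444
rmse_train: 0.166
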