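criterion,weight
acc,0.964825438
sen,0.804398756
spe,0.985470611
f1,0.951881312
fnr,-1.420375792
fpr,-1.473036988
pre,1.02152041
mcc,0.49110277
err,-1.294287661
n_params,-0.031498856
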