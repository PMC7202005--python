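poly,mono,printed_delta_um,printed_p
mel,sim,5.2,2.2e-16
yak,ere,1.6,0.017
car,sig,-1.4,0.018
hyd,mea,-0.70,0.065
ame,vir,-0.70,0.0755
nic,mul,0.56,0.1145
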