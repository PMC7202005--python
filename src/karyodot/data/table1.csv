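species,abbreviation,pct_heterochromatin,has_common_inversions,mean_distance_um,n_out,n_total,proportion_out,mean_dot_area_um2
D. virilis,vir,44,False,7.17,38,280,0.15,0.29
D. americana,ame,26,True,6.47,38,192,0.20,0.30
D. sechellia,sec,24,False,7.81,33,185,0.18,0.39
D. melanogaster,mel,24,True,11.33,71,147,0.48,0.85
D. yakuba,yak,23,True,7.48,31,92,0.34,0.70
D. hydei,hyd,22,True,4.74,31,330,0.09,0.15
D. simulans,sim,17,False,6.15,35,80,0.44,0.64
D. pseudoobscura,pse,14,True,5.67,35,220,0.16,0.34
D. erecta,ere,9,False,5.93,30,269,0.11,0.26
D. cardini,car,,True,8.40,34,120,0.28,0.72
D. meridiana,mea,,False,5.44,34,209,0.16,0.29
D. mulleri,mul,,False,5.37,37,160,0.23,0.39
D. nigricruria,nic,,True,5.93,34,240,0.14,0.22
D. similis,sig,,False,9.83,33,70,0.47,2.01
D. willistoni,wil,12,True,,14,115,0.12,
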