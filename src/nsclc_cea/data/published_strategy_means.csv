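country,scenario,strategy,cost,qaly
US,base,all_chemo,153551,0.88
US,base,all_combo,256421,1.66
US,base,test_1pct,234795,1.93
US,base,test_50pct,194801,1.80
US,pembro_minus_15,all_chemo,145615,0.88
US,pembro_minus_15,all_combo,237363,1.66
US,pembro_minus_40,all_chemo,132388,0.88
US,pembro_minus_40,all_combo,205600,1.66
CN,base,all_chemo,61072,0.78
CN,base,all_combo,115637,1.37
CN,base,test_1pct,103817,1.53
CN,base,test_50pct,83081,1.42
CN,pembro_minus_50,all_chemo,46942,0.78
CN,pembro_minus_50,all_combo,81934,1.37
CN,pembro_minus_50,test_1pct,74209,1.53
CN,pembro_minus_50,test_50pct,61011,1.42
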