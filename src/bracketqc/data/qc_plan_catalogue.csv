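plan_id,startup_rule,monitor_rule
1,1_2.5s N1,1_3s N1
2,1_3s N2,1_3s N1
3,1_2s N1,1_3s N1
4,MR N4,1_3s N2
5,1_3s N4,1_2.5s N1
6,MR N4,1_3s N4
7,1_3s N4,1_3s N1
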