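parameter,analyzer,plan_id,category,status
NT-proBNP,Cobas_Pro_1,3,D,assigned
NT-proBNP,Cobas_Pro_2,4,D,assigned
Procalcitonin,Cobas_Pro_1,1,E,assigned
Procalcitonin,Cobas_Pro_2,3,E,assigned
Troponin T,Cobas_Pro_1,1,D,assigned
Troponin T,Cobas_Pro_2,1,D,assigned
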