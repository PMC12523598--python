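parameter,analyzer,sigma,censored_ge6,available
NT-proBNP,Cobas_Pro_1,4.97,False,True
NT-proBNP,Cobas_Pro_2,4.21,False,True
Procalcitonin,Cobas_Pro_1,6.0,True,True
Procalcitonin,Cobas_Pro_2,4.91,False,True
Troponin T,Cobas_Pro_1,6.0,True,True
Troponin T,Cobas_Pro_2,6.0,True,True
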