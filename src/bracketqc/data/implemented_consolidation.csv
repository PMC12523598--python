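analyzer,general_plan_id,individualized_plan_id,parameter
Alinity_c1,3,4,Chloride
Alinity_c2,2,5,Creatinine
Alinity_c2,2,6,GGT
Alinity_c2,2,6,Total Protein
Alinity_c3,3,4,AST
Alinity_c3,3,4,Magnesium
Alinity_c3,3,7,Chloride
Alinity_c3,3,7,Uric Acid
Alinity_c4,2,7,Magnesium
Alinity_c4,2,4,Triglyceride
Alinity_c4,2,4,HDL
Cobas_Pro_1,3,,
Cobas_Pro_2,3,4,NT-proBNP
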