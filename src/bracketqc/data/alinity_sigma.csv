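parameter,analyzer,sigma,censored_ge6,available
Albumin,Alinity_c1,6.0,True,True
Albumin,Alinity_c2,6.0,True,True
Albumin,Alinity_c3,5.74,False,True
Albumin,Alinity_c4,6.0,True,True
AP,Alinity_c1,6.0,True,True
AP,Alinity_c2,5.26,False,True
AP,Alinity_c3,6.0,True,True
AP,Alinity_c4,5.66,False,True
ALT,Alinity_c1,6.0,True,True
ALT,Alinity_c2,6.0,True,True
ALT,Alinity_c3,6.0,True,True
ALT,Alinity_c4,6.0,True,True
Amylase,Alinity_c1,,False,False
Amylase,Alinity_c2,5.39,False,True
Amylase,Alinity_c3,5.90,False,True
Amylase,Alinity_c4,,False,False
AST,Alinity_c1,6.0,True,True
AST,Alinity_c2,,False,False
AST,Alinity_c3,4.38,False,True
AST,Alinity_c4,5.52,False,True
Calcium,Alinity_c1,6.0,True,True
Calcium,Alinity_c2,5.82,False,True
Calcium,Alinity_c3,5.14,False,True
Calcium,Alinity_c4,5.82,False,True
Cholesterol,Alinity_c1,,False,False
Cholesterol,Alinity_c2,5.24,False,True
Cholesterol,Alinity_c3,4.92,False,True
Cholesterol,Alinity_c4,5.65,False,True
Chloride,Alinity_c1,4.14,False,True
Chloride,Alinity_c2,3.31,False,True
Chloride,Alinity_c3,4.63,False,True
Chloride,Alinity_c4,,False,False
CK,Alinity_c1,,False,False
CK,Alinity_c2,6.0,True,True
CK,Alinity_c3,6.0,True,True
CK,Alinity_c4,6.0,True,True
Creatinine,Alinity_c1,6.0,True,True
Creatinine,Alinity_c2,5.00,False,True
Creatinine,Alinity_c3,5.42,False,True
Creatinine,Alinity_c4,5.45,False,True
Direct Bilirubin,Alinity_c1,5.15,False,True
Direct Bilirubin,Alinity_c2,,False,False
Direct Bilirubin,Alinity_c3,5.03,False,True
Direct Bilirubin,Alinity_c4,,False,False
GGT,Alinity_c1,6.0,True,True
GGT,Alinity_c2,4.19,False,True
GGT,Alinity_c3,6.0,True,True
GGT,Alinity_c4,6.0,True,True
Glucose,Alinity_c1,5.20,False,True
Glucose,Alinity_c2,6.0,True,True
Glucose,Alinity_c3,6.0,True,True
Glucose,Alinity_c4,6.0,True,True
HDL,Alinity_c1,,False,False
HDL,Alinity_c2,,False,False
HDL,Alinity_c3,,False,False
HDL,Alinity_c4,4.43,False,True
LD,Alinity_c1,3.69,False,True
LD,Alinity_c2,,False,False
LD,Alinity_c3,3.93,False,True
LD,Alinity_c4,5.58,False,True
Magnesium,Alinity_c1,3.39,False,True
Magnesium,Alinity_c2,,False,False
Magnesium,Alinity_c3,4.36,False,True
Magnesium,Alinity_c4,4.68,False,True
CRP,Alinity_c1,5.00,False,True
CRP,Alinity_c2,5.83,False,True
CRP,Alinity_c3,5.27,False,True
CRP,Alinity_c4,5.86,False,True
Potassium,Alinity_c1,5.94,False,True
Potassium,Alinity_c2,5.91,False,True
Potassium,Alinity_c3,6.0,True,True
Potassium,Alinity_c4,,False,False
Sodium,Alinity_c1,3.16,False,True
Sodium,Alinity_c2,3.66,False,True
Sodium,Alinity_c3,3.48,False,True
Sodium,Alinity_c4,,False,False
Total Bilirubin,Alinity_c1,6.0,True,True
Total Bilirubin,Alinity_c2,6.0,True,True
Total Bilirubin,Alinity_c3,6.0,True,True
Total Bilirubin,Alinity_c4,6.0,True,True
Total Protein,Alinity_c1,5.89,False,True
Total Protein,Alinity_c2,4.05,False,True
Total Protein,Alinity_c3,3.74,False,True
Total Protein,Alinity_c4,5.39,False,True
Triglyceride,Alinity_c1,6.0,True,True
Triglyceride,Alinity_c2,,False,False
Triglyceride,Alinity_c3,5.59,False,True
Triglyceride,Alinity_c4,4.51,False,True
Urea,Alinity_c1,6.0,True,True
Urea,Alinity_c2,6.0,True,True
Urea,Alinity_c3,5.11,False,True
Urea,Alinity_c4,5.94,False,True
Uric Acid,Alinity_c1,,False,False
Uric Acid,Alinity_c2,5.18,False,True
Uric Acid,Alinity_c3,4.47,False,True
Uric Acid,Alinity_c4,,False,False
Albumin U,Alinity_c1,,False,False
Albumin U,Alinity_c2,6.0,True,True
Albumin U,Alinity_c3,,False,False
Albumin U,Alinity_c4,,False,False
Calcium U,Alinity_c1,,False,False
Calcium U,Alinity_c2,6.0,True,True
Calcium U,Alinity_c3,,False,False
Calcium U,Alinity_c4,,False,False
Creatinine U,Alinity_c1,6.0,True,True
Creatinine U,Alinity_c2,6.0,True,True
Creatinine U,Alinity_c3,,False,False
Creatinine U,Alinity_c4,,False,False
Glucose U,Alinity_c1,,False,False
Glucose U,Alinity_c2,6.0,True,True
Glucose U,Alinity_c3,,False,False
Glucose U,Alinity_c4,,False,False
Phosphorus U,Alinity_c1,,False,False
Phosphorus U,Alinity_c2,5.23,False,True
Phosphorus U,Alinity_c3,,False,False
Phosphorus U,Alinity_c4,,False,False
Potassium U,Alinity_c1,6.0,True,True
Potassium U,Alinity_c2,6.0,True,True
Potassium U,Alinity_c3,,False,False
Potassium U,Alinity_c4,,False,False
Sodium U,Alinity_c1,6.0,True,True
Sodium U,Alinity_c2,5.55,False,True
Sodium U,Alinity_c3,,False,False
Sodium U,Alinity_c4,,False,False
Urea U,Alinity_c1,5.68,False,True
Urea U,Alinity_c2,5.63,False,True
Urea U,Alinity_c3,,False,False
Urea U,Alinity_c4,,False,False
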