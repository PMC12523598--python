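parameter,analyzer,plan_id,category,status
Albumin,Alinity_c1,1,B,assigned
Albumin,Alinity_c2,1,C,assigned
Albumin,Alinity_c3,1,C,assigned
Albumin,Alinity_c4,1,D,assigned
AP,Alinity_c1,1,B,assigned
AP,Alinity_c2,1,C,assigned
AP,Alinity_c3,1,C,assigned
AP,Alinity_c4,1,D,assigned
ALT,Alinity_c1,1,B,assigned
ALT,Alinity_c2,1,B,assigned
ALT,Alinity_c3,1,C,assigned
ALT,Alinity_c4,1,D,assigned
Amylase,Alinity_c1,,,not_available
Amylase,Alinity_c2,1,D,assigned
Amylase,Alinity_c3,1,E,assigned
Amylase,Alinity_c4,,,not_available
AST,Alinity_c1,1,C,assigned
AST,Alinity_c2,,,not_available
AST,Alinity_c3,4,C,assigned
AST,Alinity_c4,1,D,assigned
Calcium,Alinity_c1,1,B,assigned
Calcium,Alinity_c2,1,C,assigned
Calcium,Alinity_c3,3,C,assigned
Calcium,Alinity_c4,1,D,assigned
Cholesterol,Alinity_c1,,,not_available
Cholesterol,Alinity_c2,1,C,assigned
Cholesterol,Alinity_c3,3,E,assigned
Cholesterol,Alinity_c4,1,D,assigned
Chloride,Alinity_c1,4,E,assigned
Chloride,Alinity_c2,,E,sigma_below_4
Chloride,Alinity_c3,7,E,assigned
Chloride,Alinity_c4,,,not_available
CK,Alinity_c1,,,not_available
CK,Alinity_c2,1,D,assigned
CK,Alinity_c3,1,E,assigned
CK,Alinity_c4,1,E,assigned
Creatinine,Alinity_c1,1,A,assigned
Creatinine,Alinity_c2,5,B,assigned
Creatinine,Alinity_c3,1,C,assigned
Creatinine,Alinity_c4,1,C,assigned
Direct Bilirubin,Alinity_c1,2,E,assigned
Direct Bilirubin,Alinity_c2,,,not_available
Direct Bilirubin,Alinity_c3,3,E,assigned
Direct Bilirubin,Alinity_c4,,,not_available
GGT,Alinity_c1,1,B,assigned
GGT,Alinity_c2,6,C,assigned
GGT,Alinity_c3,1,C,assigned
GGT,Alinity_c4,1,D,assigned
Glucose,Alinity_c1,1,B,assigned
Glucose,Alinity_c2,1,B,assigned
Glucose,Alinity_c3,1,C,assigned
Glucose,Alinity_c4,1,D,assigned
HDL,Alinity_c1,,,not_available
HDL,Alinity_c2,,,not_available
HDL,Alinity_c3,,,not_available
HDL,Alinity_c4,4,D,assigned
LD,Alinity_c1,,C,sigma_below_4
LD,Alinity_c2,,,not_available
LD,Alinity_c3,,E,sigma_below_4
LD,Alinity_c4,1,E,assigned
Magnesium,Alinity_c1,,C,sigma_below_4
Magnesium,Alinity_c2,,,not_available
Magnesium,Alinity_c3,4,E,assigned
Magnesium,Alinity_c4,7,E,assigned
CRP,Alinity_c1,3,C,assigned
CRP,Alinity_c2,1,C,assigned
CRP,Alinity_c3,2,C,assigned
CRP,Alinity_c4,1,D,assigned
Potassium,Alinity_c1,1,B,assigned
Potassium,Alinity_c2,1,B,assigned
Potassium,Alinity_c3,1,A,assigned
Potassium,Alinity_c4,,,not_available
Sodium,Alinity_c1,,B,sigma_below_4
Sodium,Alinity_c2,,B,sigma_below_4
Sodium,Alinity_c3,,A,sigma_below_4
Sodium,Alinity_c4,,,not_available
Total Bilirubin,Alinity_c1,1,B,assigned
Total Bilirubin,Alinity_c2,1,C,assigned
Total Bilirubin,Alinity_c3,1,C,assigned
Total Bilirubin,Alinity_c4,1,D,assigned
Total Protein,Alinity_c1,1,C,assigned
Total Protein,Alinity_c2,6,C,assigned
Total Protein,Alinity_c3,,C,sigma_below_4
Total Protein,Alinity_c4,2,D,assigned
Triglyceride,Alinity_c1,1,C,assigned
Triglyceride,Alinity_c2,,,not_available
Triglyceride,Alinity_c3,1,E,assigned
Triglyceride,Alinity_c4,4,D,assigned
Urea,Alinity_c1,1,A,assigned
Urea,Alinity_c2,1,A,assigned
Urea,Alinity_c3,3,C,assigned
Urea,Alinity_c4,1,C,assigned
Uric Acid,Alinity_c1,,,not_available
Uric Acid,Alinity_c2,2,E,assigned
Uric Acid,Alinity_c3,7,E,assigned
Uric Acid,Alinity_c4,,,not_available
Albumin U,Alinity_c1,,,not_available
Albumin U,Alinity_c2,1,D,assigned
Albumin U,Alinity_c3,,,not_available
Albumin U,Alinity_c4,,,not_available
Calcium U,Alinity_c1,,,not_available
Calcium U,Alinity_c2,1,E,assigned
Calcium U,Alinity_c3,,,not_available
Calcium U,Alinity_c4,,,not_available
Creatinine U,Alinity_c1,1,E,assigned
Creatinine U,Alinity_c2,1,E,assigned
Creatinine U,Alinity_c3,,,not_available
Creatinine U,Alinity_c4,,,not_available
Glucose U,Alinity_c1,,,not_available
Glucose U,Alinity_c2,1,E,assigned
Glucose U,Alinity_c3,,,not_available
Glucose U,Alinity_c4,,,not_available
Phosphorus U,Alinity_c1,,,not_available
Phosphorus U,Alinity_c2,1,E,assigned
Phosphorus U,Alinity_c3,,,not_available
Phosphorus U,Alinity_c4,,,not_available
Potassium U,Alinity_c1,1,E,assigned
Potassium U,Alinity_c2,1,E,assigned
Potassium U,Alinity_c3,,,not_available
Potassium U,Alinity_c4,,,not_available
Sodium U,Alinity_c1,1,E,assigned
Sodium U,Alinity_c2,1,E,assigned
Sodium U,Alinity_c3,,,not_available
Sodium U,Alinity_c4,,,not_available
Urea U,Alinity_c1,1,E,assigned
Urea U,Alinity_c2,1,E,assigned
Urea U,Alinity_c3,,,not_available
Urea U,Alinity_c4,,,not_available
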