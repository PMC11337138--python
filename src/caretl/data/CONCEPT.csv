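concept_id,concept_name,domain_id,vocabulary_id,concept_code,standard_concept
0,No matching concept,Metadata,None,No matching concept,
8507,MALE,Gender,Gender,M,S
8532,FEMALE,Gender,Gender,F,S
38004247,Ambulatory Primary Care Clinic/Center,Visit,Visit,APCC,S
32817,EHR,Type,Type Concept,EHR,S
32856,Lab,Type,Type Concept,Lab,S
32838,EHR prescription,Type,Type Concept,EHR prescription,S
44818701,EHR physical examination,Type,Type Concept,EHR physical examination,S
45900001,Consultation reason note,Type,Type Concept,Consultation reason note,S
45900002,Consultation interview note,Type,Type Concept,Consultation interview note,S
45900003,Outcome diagnosis note,Type,Type Concept,Outcome diagnosis note,S
45900004,Referral note,Type,Type Concept,Referral note,S
45900005,Vaccination note,Type,Type Concept,Vaccination note,S
45900006,Free-text medical history note,Type,Type Concept,Free-text medical history note,S
45900007,External clinical report,Type,Type Concept,External clinical report,S
45900008,Supplementary information note,Type,Type Concept,Supplementary information note,S
45100001,Type 2 diabetes mellitus,Condition,ICD10,E11,S
45100002,Essential (primary) hypertension,Condition,ICD10,I10,S
45100003,Asthma,Condition,ICD10,J45,S
45100004,Disorders of lipoprotein metabolism,Condition,ICD10,E78,S
45100005,Other anxiety disorders,Condition,ICD10,F41,S
45100006,Dorsalgia,Condition,ICD10,M54,S
45100007,Gastro-oesophageal reflux disease,Condition,ICD10,K21,S
45100008,Other hypothyroidism,Condition,ICD10,E03,S
45100009,Migraine,Condition,ICD10,G43,S
45100010,Other disorders of urinary system,Condition,ICD10,N39,S
45100011,General examination without complaint,Condition,ICD10,Z00,S
45100012,Headache,Condition,ICD10,R51,S
45100013,Malignant neoplasm of breast,Condition,ICD10,C50,S
45100014,Obesity,Condition,ICD10,E66,S
45100015,Acute upper respiratory infections,Condition,ICD10,J06,S
45200001,Creatinine [Mass/volume] in Serum or Plasma,Measurement,LOINC,2160-0,S
45200002,Potassium [Moles/volume] in Serum or Plasma,Measurement,LOINC,2823-3,S
45200003,C reactive protein [Mass/volume] in Serum or Plasma,Measurement,LOINC,1988-5,S
45200004,Glucose [Moles/volume] in Serum or Plasma,Measurement,LOINC,14749-6,S
45200005,Hemoglobin [Mass/volume] in Blood,Measurement,LOINC,718-7,S
45200006,Sodium [Moles/volume] in Serum or Plasma,Measurement,LOINC,2951-2,S
45200007,Calcium [Mass/volume] in Serum or Plasma,Measurement,LOINC,17861-6,S
45200008,Thyrotropin [Units/volume] in Serum or Plasma,Measurement,LOINC,3016-3,S
45200009,Alanine aminotransferase [Enzymatic activity/volume],Measurement,LOINC,1742-6,S
45200010,Urea nitrogen [Mass/volume] in Serum or Plasma,Measurement,LOINC,3094-0,S
45200011,Erythrocytes [#/volume] in Blood,Measurement,LOINC,789-8,S
45200012,Leukocytes [#/volume] in Blood,Measurement,LOINC,6690-2,S
45200013,Platelets [#/volume] in Blood,Measurement,LOINC,777-3,S
45200014,Cholesterol [Mass/volume] in Serum or Plasma,Measurement,LOINC,2093-3,S
45200015,Triglyceride [Mass/volume] in Serum or Plasma,Measurement,LOINC,2571-8,S
45300001,Body weight,Measurement,SNOMED,27113001,S
45300002,Body height,Measurement,SNOMED,50373000,S
45300003,Heart rate,Measurement,SNOMED,364075005,S
45300004,Systolic blood pressure,Measurement,SNOMED,271649006,S
45300005,Diastolic blood pressure,Measurement,SNOMED,271650006,S
45300006,Body mass index,Measurement,SNOMED,60621009,S
45400001,kilogram,Unit,UCUM,kg,S
45400002,centimeter,Unit,UCUM,cm,S
45400003,per minute,Unit,UCUM,/min,S
45400004,millimeter mercury column,Unit,UCUM,mm[Hg],S
45400005,millimole per liter,Unit,UCUM,mmol/L,S
45400006,milligram per deciliter,Unit,UCUM,mg/dL,S
45400007,gram per deciliter,Unit,UCUM,g/dL,S
45400008,milligram per liter,Unit,UCUM,mg/L,S
45400009,percent,Unit,UCUM,%,S
45400010,gram per liter,Unit,UCUM,g/L,S
45500001,metformin,Drug,ATC,A10BA02,
45500002,ramipril,Drug,ATC,C09AA05,
45500003,paracetamol,Drug,ATC,N02BE01,
45500004,amoxicillin,Drug,ATC,J01CA04,
45500005,atorvastatin,Drug,ATC,C10AA05,
45500006,salbutamol,Drug,ATC,R03AC02,
45500007,sertraline,Drug,ATC,N06AB06,
45500008,acetylsalicylic acid,Drug,ATC,B01AC06,
45500009,amoxicillin and beta-lactamase inhibitor,Drug,ATC,J01CR02,
45500010,omeprazole,Drug,ATC,A02BC01,
45500011,atenolol,Drug,ATC,C07AB03,
45500012,lorazepam,Drug,ATC,N05BA06,
45600001,metformin,Drug,RxNorm,6809,S
45600002,ramipril,Drug,RxNorm,35296,S
45600003,acetaminophen,Drug,RxNorm,161,S
45600004,amoxicillin,Drug,RxNorm,723,S
45600005,atorvastatin,Drug,RxNorm,83367,S
45600006,albuterol,Drug,RxNorm,435,S
45600007,sertraline,Drug,RxNorm,36437,S
45600008,aspirin,Drug,RxNorm,1191,S
45600009,clavulanate,Drug,RxNorm,48203,S
45600010,amoxicillin / clavulanate,Drug,RxNorm,19711,S
45600011,omeprazole,Drug,RxNorm,7646,S
45600012,atenolol,Drug,RxNorm,1202,S
45600013,lorazepam,Drug,RxNorm,6470,S
45700001,SPECIALITE PHARMACEUTIQUE 01,Drug,CIP,3400930000000,
45700002,SPECIALITE PHARMACEUTIQUE 02,Drug,CIP,3400930000001,
45700003,SPECIALITE PHARMACEUTIQUE 03,Drug,CIP,3400930000002,
45700004,SPECIALITE PHARMACEUTIQUE 04,Drug,CIP,3400930000003,
45700005,SPECIALITE PHARMACEUTIQUE 05,Drug,CIP,3400930000004,
45700006,SPECIALITE PHARMACEUTIQUE 06,Drug,CIP,3400930000005,
45700007,SPECIALITE PHARMACEUTIQUE 07,Drug,CIP,3400930000006,
45700008,SPECIALITE PHARMACEUTIQUE 08,Drug,CIP,3400930000007,
45700009,SPECIALITE PHARMACEUTIQUE 09,Drug,CIP,3400930000008,
45700010,SPECIALITE PHARMACEUTIQUE 10,Drug,CIP,3400930000009,
45700011,SPECIALITE PHARMACEUTIQUE 11,Drug,CIP,3400930000010,
45700012,SPECIALITE PHARMACEUTIQUE 12,Drug,CIP,3400930000011,
45700013,SPECIALITE PHARMACEUTIQUE 13,Drug,CIP,3400930000012,
45700014,SPECIALITE PHARMACEUTIQUE 14,Drug,CIP,3400930000013,
45700015,SPECIALITE PHARMACEUTIQUE 15,Drug,CIP,3400930000014,
45700016,SPECIALITE PHARMACEUTIQUE 16,Drug,CIP,3400930000015,
45700017,SPECIALITE PHARMACEUTIQUE 17,Drug,CIP,3400930000016,
45700018,SPECIALITE PHARMACEUTIQUE 18,Drug,CIP,3400930000017,
45700019,SPECIALITE PHARMACEUTIQUE 19,Drug,CIP,3400930000018,
45700020,SPECIALITE PHARMACEUTIQUE 20,Drug,CIP,3400930000019,
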