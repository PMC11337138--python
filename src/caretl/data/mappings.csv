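normalized_label,feature,source_vocabulary,target_vocabulary,domain,annotator_a,annotator_b,adjudicator
m,sex,local,Gender,Gender,8507,8507,
f,sex,local,Gender,Gender,8532,8532,
poids,biometric,local,SNOMED,Measurement,45300001,45300001,
taille,biometric,local,SNOMED,Measurement,45300002,45300002,
frequence cardiaque,biometric,local,SNOMED,Measurement,45300003,45300003,
pa systolique,biometric,local,SNOMED,Measurement,45300004,45300003,45300004
creatinine,laboratory,local,LOINC,Measurement,45200001,45200001,
create,laboratory,local,LOINC,Measurement,45200001,45200004,45200001
potassium,laboratory,local,LOINC,Measurement,45200002,45200002,
potassium mmol l,laboratory,local,LOINC,Measurement,45200002,45200002,
c-reactive protein,laboratory,local,LOINC,Measurement,45200003,45200003,
glucose,laboratory,local,LOINC,Measurement,45200004,45200004,
glycemie,laboratory,local,LOINC,Measurement,45200004,45200004,
hemoglobine,laboratory,local,LOINC,Measurement,45200005,45200005,
sodium,laboratory,local,LOINC,Measurement,45200006,45200006,
kg,unit,local,UCUM,Unit,45400001,45400001,
cm,unit,local,UCUM,Unit,45400002,45400002,
bpm,unit,local,UCUM,Unit,45400003,45400003,
mmhg,unit,local,UCUM,Unit,45400004,45400004,
mmol l,unit,local,UCUM,Unit,45400005,45400005,
mg dl,unit,local,UCUM,Unit,45400006,45400008,45400006
g dl,unit,local,UCUM,Unit,45400007,45400007,
mg l,unit,local,UCUM,Unit,45400008,45400008,
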