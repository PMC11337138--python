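vocabulary_id,vocabulary_name
None,OMOP Standardized Vocabularies placeholder
Gender,OMOP Gender
Visit,OMOP Visit
Type Concept,OMOP Type Concept
ICD10,"International Classification of Diseases, Tenth Revision"
LOINC,Logical Observation Identifiers Names and Codes
SNOMED,Systematized Nomenclature of Medicine
UCUM,Unified Code for Units of Measure
ATC,Anatomical Therapeutic Chemical classification
RxNorm,RxNorm
CIP,Code Identifiant de Presentation (local drug codes)
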