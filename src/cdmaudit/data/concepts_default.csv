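concept_id,concept_name,vocabulary_id,domain_id
0,No matching concept,None,Metadata
8507,Male,Gender,Gender
8532,Female,Gender,Gender
38003585,Korean,Race,Race
38003564,Not Hispanic or Latino,Ethnicity,Ethnicity
9201,Inpatient visit,Visit,Visit
9202,Outpatient visit,Visit,Visit
9203,Emergency room visit,Visit,Visit
9205,Health examination,Visit,Visit
32037,Intensive care,Visit,Visit
4060985,Inflammatory disorder of the digestive tract,SNOMED,Condition
320128,Essential hypertension,SNOMED,Condition
4149481,Gastritis,SNOMED,Condition
201826,Type 2 diabetes mellitus,SNOMED,Condition
255573,Chronic obstructive lung disease,SNOMED,Condition
4329847,Myocardial infarction,SNOMED,Condition
21600001,100-mL sodium chloride 9-mg/mL injectable solution,RxNorm Extension,Drug
21600002,"10,000-mL oxygen gas for inhalation",RxNorm Extension,Drug
21600003,Artemisia argyi leaf extract 60-mg oral tablet,RxNorm Extension,Drug
21600004,Acetaminophen 500-mg oral tablet (local pack),RxNorm Extension,Drug
19000001,Metformin 500-mg oral tablet,RxNorm,Drug
19000002,Aspirin 100-mg oral tablet,RxNorm,Drug
600001,Local compounded infusion,OMOP Extension,Drug
600002,Local topical preparation,OMOP Extension,Drug
700001,Local formulary drug code,KDC,Drug
3000001,Hemoglobin (mass per volume) in blood by calculation,LOINC,Measurement
3000002,Alanine aminotransferase (enzymatic activity per volume) in serum or plasma,LOINC,Measurement
3000003,Aspartate aminotransferase (enzymatic activity per volume) in serum or plasma,LOINC,Measurement
3000004,Creatinine (mass per volume) in serum or plasma,LOINC,Measurement
3000005,Glucose (mass per volume) in serum or plasma,LOINC,Measurement
4000001,Systolic blood pressure,SNOMED,Measurement
4000002,Body weight,SNOMED,Measurement
600101,Local laboratory panel,OMOP Extension,Measurement
700101,Local measurement code,KCD7,Measurement
4000101,Tobacco smoking status,SNOMED,Observation
4000102,Alcohol intake finding,SNOMED,Observation
4000103,Dietary finding,SNOMED,Observation
3000101,Body height note,LOINC,Observation
700201,Local observation code,KCD7,Observation
4000201,Appendectomy,SNOMED,Procedure
4000202,Colonoscopy,SNOMED,Procedure
600201,Local procedure bundle A,OMOP Extension,Procedure
600202,Local procedure bundle B,OMOP Extension,Procedure
700301,Local procedure code,KCD7,Procedure
4000301,Blood specimen collection,SNOMED,Specimen
4000401,Cardiac arrest,SNOMED,Condition
4000402,Pneumonia,SNOMED,Condition
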