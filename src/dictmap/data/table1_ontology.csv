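Class ID,Preferred Label,Synonyms,Definitions,Parents
T1:C01,Race,,,
T1:C02,Hispanic or Latino,,,
T1:C03,Computed Ethnicity Code,,,
T1:C04,Computed Ethnicity Source Code,,,
T1:C05,Sex,,,
T1:C06,Birth Date,,,
T1:C07,Birth State Code,,,
T1:C08,Birth Country Code,,,
T1:C09,Date of Last Contact,,,
T1:C10,Vital Status,,,
T1:C11,City,,,
T1:C12,US State,,,
T1:C13,Postal Code,,,
T1:C14,Cause of Death,,,
T1:C15,Autopsy Indicator,,,
T1:C16,Patient Identifier,,,
T1:C17,Marital Status Code at Diagnosis,,,
T1:C18,Age at Diagnosis,,,
T1:C19,Rural-Urban Continuum Code 2003,,,
T1:C20,Census Tract,,,
T1:C21,Rural-Urban Continuum Codes 2013,,,
T1:C22,Initial Cancer Diagnosis Date,,,
T1:C23,Primary Site of Disease,,,
T1:C24,Laterality,,,
T1:C25,Histology Type Code ICD-O-3,,,
T1:C26,Diagnostic Confirmation Code,,,
T1:C27,Reporting Source Type Code,,,
T1:C28,Class of Case,,,
T1:C29,Primary Healthcare Payer,,,
T1:C30,Number of Regional Lymph Nodes Positive,,,
T1:C31,Number of Regional Lymph Nodes Examined,,,
T1:C32,Surgical Margin,,,
T1:C33,Vendor Name,,,
T1:C34,Last Follow-up Source Type Code,,,
T1:C35,Location of Death,,,
T1:C36,Occupation,,,
T1:C37,AJCC v7-Primary Tumor (T),,,
T1:C38,Tumor Size Measurement,,,
T1:C39,AJCC v6 Stage,,,
T1:C40,Number of Primary Tumors in this Location,,,
T1:C41,Is Lymphatic Invasion Present,,,
T1:C42,SEER Summary Stage 2000,,,
T1:C43,Cancer Registry Identifier,,,
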