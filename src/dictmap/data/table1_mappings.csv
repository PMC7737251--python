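variable_id,variable_name,mapping_status,concept_id,concept_preferred_label,mapped_by,mapped_at,n_comments
Race 1,Race 1,M,T1:C01,Race,kcr_expert,2020-12-15T00:00:00.000000Z,0
Race 2,Race 2,M,T1:C01,Race,kcr_expert,2020-12-15T00:00:00.000000Z,0
Race 3,Race 3,M,T1:C01,Race,kcr_expert,2020-12-15T00:00:00.000000Z,0
Race 4,Race 4,M,T1:C01,Race,kcr_expert,2020-12-15T00:00:00.000000Z,0
Race 5,Race 5,M,T1:C01,Race,kcr_expert,2020-12-15T00:00:00.000000Z,0
Spanish/Hispanic Origin,Spanish/Hispanic Origin,M,T1:C02,Hispanic or Latino,kcr_expert,2020-12-15T00:00:00.000000Z,0
Computed Ethnicity,Computed Ethnicity,M,T1:C03,Computed Ethnicity Code,kcr_expert,2020-12-15T00:00:00.000000Z,0
Computed Ethnicity Source,Computed Ethnicity Source,M,T1:C04,Computed Ethnicity Source Code,kcr_expert,2020-12-15T00:00:00.000000Z,0
Sex,Sex,M,T1:C05,Sex,kcr_expert,2020-12-15T00:00:00.000000Z,0
Date Of Birth,Date Of Birth,M,T1:C06,Birth Date,kcr_expert,2020-12-15T00:00:00.000000Z,0
Birthplace-State,Birthplace-State,M,T1:C07,Birth State Code,kcr_expert,2020-12-15T00:00:00.000000Z,0
Birthplace-Country,Birthplace-Country,M,T1:C08,Birth Country Code,kcr_expert,2020-12-15T00:00:00.000000Z,0
Date Of Last Contact,Date Of Last Contact,M,T1:C09,Date of Last Contact,kcr_expert,2020-12-15T00:00:00.000000Z,0
Vital Status,Vital Status,M,T1:C10,Vital Status,kcr_expert,2020-12-15T00:00:00.000000Z,0
Addr Current-City,Addr Current-City,M,T1:C11,City,kcr_expert,2020-12-15T00:00:00.000000Z,0
Addr Current-State,Addr Current-State,M,T1:C12,US State,kcr_expert,2020-12-15T00:00:00.000000Z,0
Addr Current-Postal Code,Addr Current-Postal Code,M,T1:C13,Postal Code,kcr_expert,2020-12-15T00:00:00.000000Z,0
Cause Of Death,Cause Of Death,M,T1:C14,Cause of Death,kcr_expert,2020-12-15T00:00:00.000000Z,0
Autopsy,Autopsy,M,T1:C15,Autopsy Indicator,kcr_expert,2020-12-15T00:00:00.000000Z,0
Patient System Id-Hosp,Patient System Id-Hosp,M,T1:C16,Patient Identifier,kcr_expert,2020-12-15T00:00:00.000000Z,0
Marital Status At Dx,Marital Status At Dx,M,T1:C17,Marital Status Code at Diagnosis,kcr_expert,2020-12-15T00:00:00.000000Z,0
Age At Diagnosis,Age At Diagnosis,M,T1:C18,Age at Diagnosis,kcr_expert,2020-12-15T00:00:00.000000Z,0
Ruralurban Continuum 2003,Ruralurban Continuum 2003,M,T1:C19,Rural-Urban Continuum Code 2003,kcr_expert,2020-12-15T00:00:00.000000Z,0
Census Tract 2010,Census Tract 2010,M,T1:C20,Census Tract,kcr_expert,2020-12-15T00:00:00.000000Z,0
Ruralurban Continuum 2013,Ruralurban Continuum 2013,M,T1:C21,Rural-Urban Continuum Codes 2013,kcr_expert,2020-12-15T00:00:00.000000Z,0
Date Of Diagnosis,Date Of Diagnosis,M,T1:C22,Initial Cancer Diagnosis Date,kcr_expert,2020-12-15T00:00:00.000000Z,0
Primary Site,Primary Site,M,T1:C23,Primary Site of Disease,kcr_expert,2020-12-15T00:00:00.000000Z,0
Laterality,Laterality,M,T1:C24,Laterality,kcr_expert,2020-12-15T00:00:00.000000Z,0
Histologic Type Icd-O-3,Histologic Type Icd-O-3,M,T1:C25,Histology Type Code ICD-O-3,kcr_expert,2020-12-15T00:00:00.000000Z,0
Diagnostic Confirmation,Diagnostic Confirmation,M,T1:C26,Diagnostic Confirmation Code,kcr_expert,2020-12-15T00:00:00.000000Z,0
Type Of Reporting Source,Type Of Reporting Source,M,T1:C27,Reporting Source Type Code,kcr_expert,2020-12-15T00:00:00.000000Z,0
Class Of Case,Class Of Case,M,T1:C28,Class of Case,kcr_expert,2020-12-15T00:00:00.000000Z,0
Primary Payer At Dx,Primary Payer At Dx,M,T1:C29,Primary Healthcare Payer,kcr_expert,2020-12-15T00:00:00.000000Z,0
Regional Nodes Positive,Regional Nodes Positive,M,T1:C30,Number of Regional Lymph Nodes Positive,kcr_expert,2020-12-15T00:00:00.000000Z,0
Regional Nodes Examined,Regional Nodes Examined,M,T1:C31,Number of Regional Lymph Nodes Examined,kcr_expert,2020-12-15T00:00:00.000000Z,0
Rx Summ-Surgical Margins,Rx Summ-Surgical Margins,M,T1:C32,Surgical Margin,kcr_expert,2020-12-15T00:00:00.000000Z,0
Vendor Name,Vendor Name,M,T1:C33,Vendor Name,kcr_expert,2020-12-15T00:00:00.000000Z,0
Follow-Up Source,Follow-Up Source,M,T1:C34,Last Follow-up Source Type Code,kcr_expert,2020-12-15T00:00:00.000000Z,0
Place Of Death,Place Of Death,M,T1:C35,Location of Death,kcr_expert,2020-12-15T00:00:00.000000Z,0
Text-Usual Occupation,Text-Usual Occupation,M,T1:C36,Occupation,kcr_expert,2020-12-15T00:00:00.000000Z,0
Tnm Clin T,Tnm Clin T,M,T1:C37,AJCC v7-Primary Tumor (T),kcr_expert,2020-12-15T00:00:00.000000Z,0
Tumor Size Summary,Tumor Size Summary,M,T1:C38,Tumor Size Measurement,kcr_expert,2020-12-15T00:00:00.000000Z,0
Derived Ajcc-6 Stage Grp,Derived Ajcc-6 Stage Grp,M,T1:C39,AJCC v6 Stage,kcr_expert,2020-12-15T00:00:00.000000Z,0
Multiplicity Counter,Multiplicity Counter,M,T1:C40,Number of Primary Tumors in this Location,kcr_expert,2020-12-15T00:00:00.000000Z,0
Lymph-Vascular Invasion,Lymph-Vascular Invasion,M,T1:C41,Is Lymphatic Invasion Present,kcr_expert,2020-12-15T00:00:00.000000Z,0
Seer Summary Stage 2000,Seer Summary Stage 2000,M,T1:C42,SEER Summary Stage 2000,kcr_expert,2020-12-15T00:00:00.000000Z,0
Registry Id,Registry Id,M,T1:C43,Cancer Registry Identifier,kcr_expert,2020-12-15T00:00:00.000000Z,0
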