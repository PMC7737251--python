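variable_id,variable_name,concept_id
Race 1,Race 1,T1:C01
Race 2,Race 2,T1:C01
Race 3,Race 3,T1:C01
Race 4,Race 4,T1:C01
Race 5,Race 5,T1:C01
Spanish/Hispanic Origin,Spanish/Hispanic Origin,T1:C02
Computed Ethnicity,Computed Ethnicity,T1:C03
Computed Ethnicity Source,Computed Ethnicity Source,T1:C04
Sex,Sex,T1:C05
Date Of Birth,Date Of Birth,T1:C06
Birthplace-State,Birthplace-State,T1:C07
Birthplace-Country,Birthplace-Country,T1:C08
Date Of Last Contact,Date Of Last Contact,T1:C09
Vital Status,Vital Status,T1:C10
Addr Current-City,Addr Current-City,T1:C11
Addr Current-State,Addr Current-State,T1:C12
Addr Current-Postal Code,Addr Current-Postal Code,T1:C13
Cause Of Death,Cause Of Death,T1:C14
Autopsy,Autopsy,T1:C15
Patient System Id-Hosp,Patient System Id-Hosp,T1:C16
Marital Status At Dx,Marital Status At Dx,T1:C17
Age At Diagnosis,Age At Diagnosis,T1:C18
Ruralurban Continuum 2003,Ruralurban Continuum 2003,T1:C19
Census Tract 2010,Census Tract 2010,T1:C20
Ruralurban Continuum 2013,Ruralurban Continuum 2013,T1:C21
Date Of Diagnosis,Date Of Diagnosis,T1:C22
Primary Site,Primary Site,T1:C23
Laterality,Laterality,T1:C24
Histologic Type Icd-O-3,Histologic Type Icd-O-3,T1:C25
Diagnostic Confirmation,Diagnostic Confirmation,T1:C26
Type Of Reporting Source,Type Of Reporting Source,T1:C27
Class Of Case,Class Of Case,T1:C28
Primary Payer At Dx,Primary Payer At Dx,T1:C29
Regional Nodes Positive,Regional Nodes Positive,T1:C30
Regional Nodes Examined,Regional Nodes Examined,T1:C31
Rx Summ-Surgical Margins,Rx Summ-Surgical Margins,T1:C32
Vendor Name,Vendor Name,T1:C33
Follow-Up Source,Follow-Up Source,T1:C34
Place Of Death,Place Of Death,T1:C35
Text-Usual Occupation,Text-Usual Occupation,T1:C36
Tnm Clin T,Tnm Clin T,T1:C37
Tumor Size Summary,Tumor Size Summary,T1:C38
Derived Ajcc-6 Stage Grp,Derived Ajcc-6 Stage Grp,T1:C39
Multiplicity Counter,Multiplicity Counter,T1:C40
Lymph-Vascular Invasion,Lymph-Vascular Invasion,T1:C41
Seer Summary Stage 2000,Seer Summary Stage 2000,T1:C42
Registry Id,Registry Id,T1:C43
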