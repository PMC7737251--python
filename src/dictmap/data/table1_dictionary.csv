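Variable
Race 1
Race 2
Race 3
Race 4
Race 5
Spanish/Hispanic Origin
Computed Ethnicity
Computed Ethnicity Source
Sex
Date Of Birth
Birthplace-State
Birthplace-Country
Date Of Last Contact
Vital Status
Addr Current-City
Addr Current-State
Addr Current-Postal Code
Cause Of Death
Autopsy
Patient System Id-Hosp
Marital Status At Dx
Age At Diagnosis
Ruralurban Continuum 2003
Census Tract 2010
Ruralurban Continuum 2013
Date Of Diagnosis
Primary Site
Laterality
Histologic Type Icd-O-3
Diagnostic Confirmation
Type Of Reporting Source
Class Of Case
Primary Payer At Dx
Regional Nodes Positive
Regional Nodes Examined
Rx Summ-Surgical Margins
Vendor Name
Follow-Up Source
Place Of Death
Text-Usual Occupation
Tnm Clin T
Tumor Size Summary
Derived Ajcc-6 Stage Grp
Multiplicity Counter
Lymph-Vascular Invasion
Seer Summary Stage 2000
Registry Id
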