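abdominal acute adjuvant admission adverse age alignment ambulatory anatomic anemia
angiogram antibody antigen aortic arterial assessment asthma atrial audit axillary
baseline behavior benign bilateral biopsy birth bladder blood body bone
brain breast cardiac care carcinoma case category cause cell census
cervical chemotherapy chest cholesterol chronic city claim class clinical code
cohort colon comorbidity confirmation consent contact continuum county creatinine criteria
cycle date death demographic diagnosis diagnostic dictionary discharge disease disorder
dose duration dysplasia education eligibility encounter endocrine enrollment entity episode
ethnicity event examination exposure facility factor family femoral finding follow
fracture frequency gastric gender genomic gland glucose grade growth health
heart hemoglobin hepatic histology history hospital identifier imaging immune incidence
index indicator infection inflammation insurance intake invasion kidney label laterality
lesion level liver location lung lymph lymphatic malignant mammogram margin
marital marker measurement medication melanoma metabolic metastasis method modality morphology
mortality mutation neck necrosis neonatal neural node nodule number occupation
oncology onset organ origin outcome ovarian pancreatic pathology patient payer
pediatric pelvic percent performance pharmacy phase physician plasma platelet population
positive postal pressure primary procedure prognosis progression prostate protein protocol
pulmonary quality race radiation range rate record recurrence referral regimen
region registry relapse renal report resection residence respiratory response result
review risk rural sample sarcoma score screening secondary section segment
sequence serum severity sex site size skin source specimen spinal
stage state status subject summary surgery surgical survival symptom syndrome
system thoracic thyroid tissue tract transfer transplant trauma treatment trial
tumor type unit urban uterine vaccine value variable vascular vendor
venous visit vital volume weight
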