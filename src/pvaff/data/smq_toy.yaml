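# Toy SMQ-style term lists for the five medical-history groups.
#
# MedDRA and its SMQ term lists are licensed and cannot be redistributed;
# this file ships a small synthetic stand-in vocabulary with the same shape
# (group -> SMQ code -> preferred terms) so the grouping machinery is fully
# exercisable. Real term lists can be dropped in with the same schema.
osteoporosis:
  - code: "20000178"
    name: Osteoporosis/osteopenia
    terms: [osteoporosis, osteopenia, postmenopausal osteoporosis, bone density decreased]
arthritis:
  - code: "20000216"
    name: Arthritis
    terms: [arthritis, rheumatoid arthritis, osteoarthritis, polyarthritis]
sle:
  - code: "20000045"
    name: Systemic lupus erythematosus
    terms: [systemic lupus erythematosus, lupus nephritis, sle]
renal_disorder:
  - code: "20000003"
    name: Acute renal failure
    terms: [acute kidney injury, renal failure, anuria]
  - code: "20000181"
    name: Renal vessel disorder
    terms: [renal artery stenosis, renal vein thrombosis]
  - code: "20000213"
    name: Chronic kidney disease
    terms: [chronic kidney disease, nephrosclerosis, renal impairment]
cancer:
  - code: "20000092"
    name: Malignant-disorder-related state
    terms: [metastasis, tumour haemorrhage]
  - code: "20000094"
    name: Tumour marker
    terms: [tumour marker increased]
  - code: "20000110"
    name: Neoplasm of the oropharynx
    terms: [oropharyngeal neoplasm]
  - code: "20000194"
    name: Malignant tumour
    terms: [malignant neoplasm, cancer]
  - code: "20000195"
    name: Tumour unidentified in detail
    terms: [neoplasm unspecified]
  - code: "20000196"
    name: Malignant biliary tract neoplasm
    terms: [bile duct cancer]
  - code: "20000197"
    name: Biliary tract neoplasm unknown in detail
    terms: [biliary neoplasm unspecified]
  - code: "20000198"
    name: Malignant breast tumour
    terms: [breast cancer, breast carcinoma]
  - code: "20000199"
    name: Breast tumour unknown in detail
    terms: [breast neoplasm unspecified]
  - code: "20000200"
    name: Malignant ovarian tumour
    terms: [ovarian cancer]
  - code: "20000201"
    name: Ovarian tumour unidentified in detail
    terms: [ovarian neoplasm unspecified]
  - code: "20000202"
    name: Malignant prostate tumour
    terms: [prostate cancer]
  - code: "20000203"
    name: Prostate tumour unidentified in detail
    terms: [prostatic neoplasm unspecified]
  - code: "20000204"
    name: Malignant skin tumour
    terms: [skin cancer, melanoma]
  - code: "20000205"
    name: Skin tumour unidentified in detail
    terms: [skin neoplasm unspecified]
  - code: "20000206"
    name: Malignant uterus/salpingioma
    terms: [uterine cancer]
  - code: "20000207"
    name: Uterus/salpingioma unidentified in detail
    terms: [uterine neoplasm unspecified]
  - code: "20000208"
    name: Malignant hepatophyma
    terms: [hepatic cancer, hepatocellular carcinoma]
  - code: "20000209"
    name: Hepatophyma unidentified in detail
    terms: [hepatic neoplasm unspecified]
  - code: "20000215"
    name: Malignant lymphoma
    terms: [lymphoma, hodgkin's disease]
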