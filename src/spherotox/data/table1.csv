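compound,class,description,assay,outcome_kind,value_uM,se_uM,max_uM
TAB,Toxic substances,Toxin,iPSC-3D,ic50,1.69,0.082,
TAB,Toxic substances,Toxin,iPSC-2D,ic50,1.22,1.02,
Methyl mercury,Toxic substances,Toxin,iPSC-3D,ic50,2.82,0.49,
Methyl mercury,Toxic substances,Toxin,iPSC-2D,ic50,5.05,1.31,
Fuzariotoxin,Toxic substances,Toxin,iPSC-3D,ic50,0.481,,
Fuzariotoxin,Toxic substances,Toxin,iPSC-2D,ic50,3.75,,
Aflatoxin B1,Toxic substances,Toxin,iPSC-3D,ic50,0.595,0.145,
Aflatoxin B1,Toxic substances,Toxin,iPSC-2D,ic50,1.7,,
Aflatoxin G1,Toxic substances,Toxin,iPSC-3D,ic50,7.78,2.13,
Aflatoxin G1,Toxic substances,Toxin,iPSC-2D,ic50,9.45,2.01,
Rotenone,Toxic substances,Pesticide,iPSC-3D,ic50,21.4,6.9,
Rotenone,Toxic substances,Pesticide,iPSC-2D,nd,,,
Mitoxantrone,Anti-proliferative agents,Topoisomerase II inhibitor,iPSC-3D,ic50,0.533,0.011,
Mitoxantrone,Anti-proliferative agents,Topoisomerase II inhibitor,iPSC-2D,ic50,3.7,0.32,
Daunorubicin,Anti-proliferative agents,"DNA-intercalator, anti-cancer",iPSC-3D,ic50,0.671,0.046,
Daunorubicin,Anti-proliferative agents,"DNA-intercalator, anti-cancer",iPSC-2D,ic50,0.5,,
Idarubicin,Anti-proliferative agents,"DNA-intercalator, anti-cancer",iPSC-3D,ic50,1.11,,
Idarubicin,Anti-proliferative agents,"DNA-intercalator, anti-cancer",iPSC-2D,ic50,0.94,,
Doxorubicin·HCl,Anti-proliferative agents,"DNA-intercalator, anti-cancer",iPSC-3D,ic50,5.69,4.04,
Doxorubicin·HCl,Anti-proliferative agents,"DNA-intercalator, anti-cancer",iPSC-2D,ic50,2.17,0.08,
Staurosporine,Anti-proliferative agents,"Kinase inhibitor, apoptosis inducer",iPSC-3D,ic50,0.91,0.12,
Staurosporine,Anti-proliferative agents,"Kinase inhibitor, apoptosis inducer",iPSC-2D,ic50,1.71,0.87,
Mitomycin C,Anti-proliferative agents,"DNA-intercalator, anti-cancer",iPSC-3D,ic50,2.28,0.25,
Mitomycin C,Anti-proliferative agents,"DNA-intercalator, anti-cancer",iPSC-2D,ic50,2.36,0.65,
Quinacrine,Other drugs,Anti-malaria,iPSC-3D,ic50,1.029,0.212,
Quinacrine,Other drugs,Anti-malaria,iPSC-2D,ic50,2.52,,
Coralgil,Other drugs,Inducer of steatosis,iPSC-3D,ic50,1.24,,
Coralgil,Other drugs,Inducer of steatosis,iPSC-2D,ic50,6.71,,
Puromycin,Other drugs,Protein synthesis inhibitor,iPSC-3D,ic50,3.82,,
Puromycin,Other drugs,Protein synthesis inhibitor,iPSC-2D,ic50,7.2,11.2,
Amlodipine,Other drugs,Ca blocker,iPSC-3D,ic50,4.12,,
Amlodipine,Other drugs,Ca blocker,iPSC-2D,ic50,30.2,,
rac Perhexiline Maleate,Other drugs,Mitochondria inhibitor,iPSC-3D,ic50,6.36,0.15,
rac Perhexiline Maleate,Other drugs,Mitochondria inhibitor,iPSC-2D,ic50,9.89,,
Tamoxifen,Other drugs,Estrogen receptor antagonist,iPSC-3D,ic50,12.4,,
Tamoxifen,Other drugs,Estrogen receptor antagonist,iPSC-2D,ic50,10.23,,
Miconazole nitrate,Other drugs,Anti-fungal,iPSC-3D,ic50,13.71,0.789,
Miconazole nitrate,Other drugs,Anti-fungal,iPSC-2D,ic50,103.1,132,
Fluphenazine di·HCl,Other drugs,Anti-psychotic,iPSC-3D,ic50,13.0,0.824,
Fluphenazine di·HCl,Other drugs,Anti-psychotic,iPSC-2D,ic50,29.5,,
Paroxetine,Other drugs,Antidepressant,iPSC-3D,ic50,14.73,3.92,
Paroxetine,Other drugs,Antidepressant,iPSC-2D,ic50,30.4,,
Thioridazine,Other drugs,Anti-psychotic,iPSC-3D,ic50,15.83,4.47,
Thioridazine,Other drugs,Anti-psychotic,iPSC-2D,ic50,31.4,,
Chloroquine,Other drugs,Anti-malaria,iPSC-3D,ic50,18.60,0.247,
Chloroquine,Other drugs,Anti-malaria,iPSC-2D,ic50,38.5,,
Ketoconazole,Other drugs,Anti-fungal,iPSC-3D,ic50,20.4,10.7,
Ketoconazole,Other drugs,Anti-fungal,iPSC-2D,ic50,61.0,46.2,
Amiodarone·HCl,Other drugs,"Anti-arrhythmia, autophagy inducer",iPSC-3D,ic50,22.6,9.68,
Amiodarone·HCl,Other drugs,"Anti-arrhythmia, autophagy inducer",iPSC-2D,ic50,15.3,18.3,
Paclitaxel,Other drugs,Microtubule inhibitor,iPSC-3D,ic50,26.2,6.39,
Paclitaxel,Other drugs,Microtubule inhibitor,iPSC-2D,no_tox,,,100
Fluoxetine,Other drugs,Antidepressant,iPSC-3D,ic50,28.9,,
Fluoxetine,Other drugs,Antidepressant,iPSC-2D,ic50,10.17,0.321,
Imatinib,Other drugs,Kinase inhibitor,iPSC-3D,ic50,36.8,,
Imatinib,Other drugs,Kinase inhibitor,iPSC-2D,nd,,,
Pimozide,Other drugs,Anti-psychotic,iPSC-3D,ic50,35.1,1.39,
Pimozide,Other drugs,Anti-psychotic,iPSC-2D,ic50,13.5,15.9,
Apigenin,Other drugs,Autophagy inducer,iPSC-3D,ic50,36.9,10.2,
Apigenin,Other drugs,Autophagy inducer,iPSC-2D,nd,,,
Haloperidol·HCl,Other drugs,Anti-psychotic,iPSC-3D,ic50,52.2,21.6,
Haloperidol·HCl,Other drugs,Anti-psychotic,iPSC-2D,no_tox,,,100
Isradipine,Other drugs,Ca blocker,iPSC-3D,ic50,168,137,
Isradipine,Other drugs,Ca blocker,iPSC-2D,nd,,,
Colchicine,Other drugs,Microtubule inhibitor,iPSC-3D,gt_max,,,100
Colchicine,Other drugs,Microtubule inhibitor,iPSC-2D,gt_max,,,100
Tolcapone,Other drugs,Parkinson disease drug,iPSC-3D,gt_max,,,100
Tolcapone,Other drugs,Parkinson disease drug,iPSC-2D,gt_max,,,100
Doxocycline,Other drugs,Antibiotic,iPSC-3D,gt_max,,,100
Doxocycline,Other drugs,Antibiotic,iPSC-2D,gt_max,,,100
Retinoic acid,Other drugs,Retinoic acid receptor agonist,iPSC-3D,approx,500,,
Retinoic acid,Other drugs,Retinoic acid receptor agonist,iPSC-2D,ic50,480,,
Imipramine,Other drugs,Antidepressant (TCA),iPSC-3D,no_tox,,,100
Imipramine,Other drugs,Antidepressant (TCA),iPSC-2D,gt_max,,,100
Carboplatin,Other drugs,"DNA repair, anti-cancer",iPSC-3D,no_tox,,,500
Carboplatin,Other drugs,"DNA repair, anti-cancer",iPSC-2D,no_tox,,,500
Cytarabine,Other drugs,"DNA intercalator, anti-cancer",iPSC-3D,no_tox,,,1000
Cytarabine,Other drugs,"DNA intercalator, anti-cancer",iPSC-2D,no_tox,,,1000
Etoposide,Other drugs,"Topoisomerase inhibitor, anti-cancer",iPSC-3D,no_tox,,,1000
Etoposide,Other drugs,"Topoisomerase inhibitor, anti-cancer",iPSC-2D,no_tox,,,1000
Phenylbutazone,Other drugs,Nonsteroidal anti-inflammatory,iPSC-3D,no_tox,,,100
Phenylbutazone,Other drugs,Nonsteroidal anti-inflammatory,iPSC-2D,no_tox,,,100
Acetaminophen,Other drugs,Nonsteroidal anti-inflammatory,iPSC-3D,no_tox,,,1000
Acetaminophen,Other drugs,Nonsteroidal anti-inflammatory,iPSC-2D,no_tox,,,1000
Penicillin V potassium salt,Negative controls,Antibiotic,iPSC-3D,no_tox,,,1000
Penicillin V potassium salt,Negative controls,Antibiotic,iPSC-2D,no_tox,,,1000
Streptomycin sulfate,Negative controls,Antibiotic,iPSC-3D,no_tox,,,1000
Streptomycin sulfate,Negative controls,Antibiotic,iPSC-2D,no_tox,,,1000
Aspirin,Negative controls,Anti-inflammatory,iPSC-3D,no_tox,,,1000
Aspirin,Negative controls,Anti-inflammatory,iPSC-2D,no_tox,,,1000
Ampicillin,Negative controls,Antibiotic,iPSC-3D,no_tox,,,1000
Ampicillin,Negative controls,Antibiotic,iPSC-2D,no_tox,,,1000
Sucrose,Negative controls,Carbohydrate,iPSC-3D,no_tox,,,1000
Sucrose,Negative controls,Carbohydrate,iPSC-2D,no_tox,,,1000
Sorbitol,Negative controls,Carbohydrate,iPSC-3D,no_tox,,,1000
Sorbitol,Negative controls,Carbohydrate,iPSC-2D,no_tox,,,1000
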