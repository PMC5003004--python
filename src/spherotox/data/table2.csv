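compound,class,description,assay,outcome_kind,value_uM,se_uM,max_uM
Idarubicin,Anti-proliferation agents,,HepG2-3D,ic50,0.00513,0.00523,
Idarubicin,Anti-proliferation agents,,iPSC-3D,ic50,1.11,,
Staurosporine,Anti-proliferation agents,,HepG2-3D,ic50,0.00582,0.00098,
Staurosporine,Anti-proliferation agents,,iPSC-3D,ic50,0.91,0.12,
Doxorubicin·HCl,Anti-proliferation agents,,HepG2-3D,ic50,0.008,0.0005,
Doxorubicin·HCl,Anti-proliferation agents,,iPSC-3D,ic50,5.69,4.04,
Mitomycin C,Anti-proliferation agents,,HepG2-3D,ic50,0.012,0.0006,
Mitomycin C,Anti-proliferation agents,,iPSC-3D,ic50,2.28,0.25,
Paclitaxel,Anti-proliferation agents,,HepG2-3D,ic50,0.01,0.0012,
Paclitaxel,Anti-proliferation agents,,iPSC-3D,ic50,26.2,6.39,
Cytarabine,Anti-proliferation agents,,HepG2-3D,ic50,0.307,0.097,
Cytarabine,Anti-proliferation agents,,iPSC-3D,no_tox,,,1000
Etoposide,Anti-proliferation agents,,HepG2-3D,ic50,4.18,2.99,
Etoposide,Anti-proliferation agents,,iPSC-3D,no_tox,,,1000
Carboplatin,Anti-proliferation agents,,HepG2-3D,ic50,15.82,2.61,
Carboplatin,Anti-proliferation agents,,iPSC-3D,no_tox,,,1000
TAB,Toxic substances,,HepG2-3D,ic50,0.005,0.0047,
TAB,Toxic substances,,iPSC-3D,ic50,1.69,0.082,
Methyl mercury,Toxic substances,,HepG2-3D,ic50,9.19,2.98,
Methyl mercury,Toxic substances,,iPSC-3D,ic50,2.82,0.49,
Rotenone,Toxic substances,,HepG2-3D,ic50,8.32,4.37,
Rotenone,Toxic substances,,iPSC-3D,ic50,21.4,6.94,
Pimozide,Other drugs,,HepG2-3D,ic50,4.73,3.18,
Pimozide,Other drugs,,iPSC-3D,ic50,35.1,1.39,
Tamoxifen,Other drugs,,HepG2-3D,ic50,18.7,29.4,
Tamoxifen,Other drugs,,iPSC-3D,ic50,12.4,13.2,
Ketoconazole,Other drugs,,HepG2-3D,ic50,19.2,12.5,
Ketoconazole,Other drugs,,iPSC-3D,ic50,20.4,10.7,
Apigenin,Other drugs,,HepG2-3D,ic50,21.9,13.4,
Apigenin,Other drugs,,iPSC-3D,ic50,36.9,10.18,
Isradipine,Other drugs,,HepG2-3D,ic50,22.17,,
Isradipine,Other drugs,,iPSC-3D,ic50,168,137,
Haloperidol·HCl,Other drugs,,HepG2-3D,ic50,25.08,5.50,
Haloperidol·HCl,Other drugs,,iPSC-3D,ic50,52.2,21.6,
Chloroquine,Other drugs,,HepG2-3D,ic50,33.28,,
Chloroquine,Other drugs,,iPSC-3D,ic50,18.60,0.247,
Amiodarone·HCl,Other drugs,,HepG2-3D,ic50,42.4,8.39,
Amiodarone·HCl,Other drugs,,iPSC-3D,ic50,22.6,9.68,
Imatinib,Other drugs,,HepG2-3D,ic50,178,40.54,
Imatinib,Other drugs,,iPSC-3D,ic50,36.8,,
Aspirin,Negative controls,,HepG2-3D,no_tox,,,1000
Aspirin,Negative controls,,iPSC-3D,no_tox,,,1000
Ampicillin,Negative controls,,HepG2-3D,no_tox,,,1000
Ampicillin,Negative controls,,iPSC-3D,no_tox,,,1000
Sucrose,Negative controls,,HepG2-3D,no_tox,,,1000
Sucrose,Negative controls,,iPSC-3D,no_tox,,,1000
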