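# Default clinical feature groups for occlusion importance.
# Values are vocabulary code lists (3-digit ICD-9-CM categories or ATC
# categories), or the literals "age" / "sex" for the auxiliary inputs.
age: age
sex: sex
autoimmune_connective_tissue: ["710"]
rheumatoid_arthritis_inflammatory_polyarthritis: ["714"]
anxiety_depression: ["300", "311"]
inflammatory_spondylopathies: ["720"]
osteoporosis_pathologic_fracture: ["733"]
atopic_dermatitis: ["691"]
menopausal_disorders: ["627"]
renal_disease: ["585", "586"]
obesity_metabolic_syndrome: ["277", "278"]
dyslipidemia: ["272"]
cardiovascular_disorders: ["410", "414", "428"]
diabetes: ["250"]
hypertension: ["401", "405"]
dmards: ["L01BA", "L04AA", "L04AD", "L04AX01", "L04AX03", "A07EC", "P01BA"]
methotrexate: ["L01BA"]
azathioprine: ["L04AX01"]
aminoquinolines: ["P01BA"]
calcineurin_inhibitors: ["L04AD"]
selective_immunosuppressants: ["L04AA"]
sulfasalazine: ["A07EC"]
topical_tars: ["D05AA"]
vitamin_d_analogues: ["D05AX02", "D05AX03"]
acitretin: ["D05BB"]
topical_corticosteroids: ["D07AC"]
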