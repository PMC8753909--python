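phecode,label,group,exclude_range
278.1,Obesity,endocrine/metabolic,278-279.99
278.4,Overweight,endocrine/metabolic,278-279.99
279.1,Abnormal weight gain,endocrine/metabolic,278-279.99
008,Intestinal infection,infectious diseases,001-009.99
038,Septicemia,infectious diseases,038-041.99
041,Bacterial infection NOS,infectious diseases,038-041.99
153,Colorectal cancer,neoplasms,150-159.99
174.1,Breast cancer,neoplasms,174-175.99
185,Prostate cancer,neoplasms,185-187.99
244,Hypothyroidism,endocrine/metabolic,240-246.99
250.2,Type 2 diabetes,endocrine/metabolic,249-250.99
272.1,Hyperlipidemia,endocrine/metabolic,272-272.99
275.5,Vitamin D deficiency,endocrine/metabolic,
285,Anemia NOS,hematopoietic,280-285.99
296.2,Depression,mental disorders,295-299.99
300.1,Anxiety disorder,mental disorders,295-302.99
327.3,Sleep apnea,neurological,327-327.99
340,Migraine,neurological,
365,Glaucoma,sense organs,360-369.99
401.1,Essential hypertension,circulatory system,401-405.99
411.4,Coronary atherosclerosis,circulatory system,410-414.99
427.2,Atrial fibrillation,circulatory system,426-427.99
428.2,Heart failure,circulatory system,428-428.99
433,Cerebrovascular disease,circulatory system,430-438.99
454.1,Varicose veins,circulatory system,454-454.99
475,Asthma,respiratory,470-478.99
496,COPD,respiratory,490-496.99
530.1,GERD,digestive,530-530.99
535,Gastritis,digestive,530-537.99
550.2,Diaphragmatic hernia,digestive,550-553.99
574.1,Cholelithiasis,digestive,574-575.99
585.3,Chronic kidney disease,genitourinary,580-589.99
600,Benign prostatic hyperplasia,genitourinary,
626.1,Menstrual disorder,genitourinary,
681,Cellulitis,dermatologic,680-686.99
696.4,Psoriasis,dermatologic,694-696.99
714.1,Rheumatoid arthritis,musculoskeletal,714-714.99
715.2,Osteoarthritis,musculoskeletal,715-716.99
735.3,Bunion,musculoskeletal,
740.1,Osteoporosis,musculoskeletal,740-743.99
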