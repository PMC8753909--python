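vocabulary,code,phecode
ICD9,278,278.1
ICD9,793.91,278.1
ICD9,V85.3,278.1
ICD9,V85.30,278.1
ICD9,V85.31,278.1
ICD9,V85.32,278.1
ICD9,V85.33,278.1
ICD9,V85.34,278.1
ICD9,V85.54,278.1
ICD10,E66.0,278.1
ICD10,E66.09,278.1
ICD10,E66.1,278.1
ICD10,E66.8,278.1
ICD10,E66.9,278.1
ICD10,R93.9,278.1
ICD10,Z68.30,278.1
ICD10,Z68.31,278.1
ICD10,Z68.32,278.1
ICD10,Z68.33,278.1
ICD10,Z68.34,278.1
ICD10,Z68.54,278.1
ICD9,278.02,278.4
ICD10,E66.3,278.4
ICD9,783.1,279.1
ICD10,R63.5,279.1
ICD9,700.1,008
ICD9,700.2,008
ICD10,Q40.0,008
ICD10,Q40.1,008
ICD9,701.1,038
ICD9,701.2,038
ICD10,Q41.0,038
ICD10,Q41.1,038
ICD9,702.1,041
ICD9,702.2,041
ICD10,Q42.0,041
ICD10,Q42.1,041
ICD9,703.1,153
ICD9,703.2,153
ICD10,Q43.0,153
ICD10,Q43.1,153
ICD9,704.1,174.1
ICD9,704.2,174.1
ICD10,Q44.0,174.1
ICD10,Q44.1,174.1
ICD9,705.1,185
ICD9,705.2,185
ICD10,Q45.0,185
ICD10,Q45.1,185
ICD9,706.1,244
ICD9,706.2,244
ICD10,Q46.0,244
ICD10,Q46.1,244
ICD9,707.1,250.2
ICD9,707.2,250.2
ICD10,Q47.0,250.2
ICD10,Q47.1,250.2
ICD9,708.1,272.1
ICD9,708.2,272.1
ICD10,Q48.0,272.1
ICD10,Q48.1,272.1
ICD9,709.1,275.5
ICD9,709.2,275.5
ICD10,Q49.0,275.5
ICD10,Q49.1,275.5
ICD9,710.1,285
ICD9,710.2,285
ICD10,Q50.0,285
ICD10,Q50.1,285
ICD9,711.1,296.2
ICD9,711.2,296.2
ICD10,Q51.0,296.2
ICD10,Q51.1,296.2
ICD9,712.1,300.1
ICD9,712.2,300.1
ICD10,Q52.0,300.1
ICD10,Q52.1,300.1
ICD9,713.1,327.3
ICD9,713.2,327.3
ICD10,Q53.0,327.3
ICD10,Q53.1,327.3
ICD9,714.1,340
ICD9,714.2,340
ICD10,Q54.0,340
ICD10,Q54.1,340
ICD9,715.1,365
ICD9,715.2,365
ICD10,Q55.0,365
ICD10,Q55.1,365
ICD9,716.1,401.1
ICD9,716.2,401.1
ICD10,Q56.0,401.1
ICD10,Q56.1,401.1
ICD9,717.1,411.4
ICD9,717.2,411.4
ICD10,Q57.0,411.4
ICD10,Q57.1,411.4
ICD9,718.1,427.2
ICD9,718.2,427.2
ICD10,Q58.0,427.2
ICD10,Q58.1,427.2
ICD9,719.1,428.2
ICD9,719.2,428.2
ICD10,Q59.0,428.2
ICD10,Q59.1,428.2
ICD9,720.1,433
ICD9,720.2,433
ICD10,Q60.0,433
ICD10,Q60.1,433
ICD9,721.1,454.1
ICD9,721.2,454.1
ICD10,Q61.0,454.1
ICD10,Q61.1,454.1
ICD9,722.1,475
ICD9,722.2,475
ICD10,Q62.0,475
ICD10,Q62.1,475
ICD9,723.1,496
ICD9,723.2,496
ICD10,Q63.0,496
ICD10,Q63.1,496
ICD9,724.1,530.1
ICD9,724.2,530.1
ICD10,Q64.0,530.1
ICD10,Q64.1,530.1
ICD9,725.1,535
ICD9,725.2,535
ICD10,Q65.0,535
ICD10,Q65.1,535
ICD9,726.1,550.2
ICD9,726.2,550.2
ICD10,Q66.0,550.2
ICD10,Q66.1,550.2
ICD9,727.1,574.1
ICD9,727.2,574.1
ICD10,Q67.0,574.1
ICD10,Q67.1,574.1
ICD9,728.1,585.3
ICD9,728.2,585.3
ICD10,Q68.0,585.3
ICD10,Q68.1,585.3
ICD9,729.1,600
ICD9,729.2,600
ICD10,Q69.0,600
ICD10,Q69.1,600
ICD9,730.1,626.1
ICD9,730.2,626.1
ICD10,Q70.0,626.1
ICD10,Q70.1,626.1
ICD9,731.1,681
ICD9,731.2,681
ICD10,Q71.0,681
ICD10,Q71.1,681
ICD9,732.1,696.4
ICD9,732.2,696.4
ICD10,Q72.0,696.4
ICD10,Q72.1,696.4
ICD9,733.1,714.1
ICD9,733.2,714.1
ICD10,Q73.0,714.1
ICD10,Q73.1,714.1
ICD9,734.1,715.2
ICD9,734.2,715.2
ICD10,Q74.0,715.2
ICD10,Q74.1,715.2
ICD9,735.1,735.3
ICD9,735.2,735.3
ICD10,Q75.0,735.3
ICD10,Q75.1,735.3
ICD9,736.1,740.1
ICD9,736.2,740.1
ICD10,Q76.0,740.1
ICD10,Q76.1,740.1
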