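Feature,D1,D2,D3,D4,D5
TSH,1,1,1,1,1
T3_measured,1,1,1,1,1
on_thyroxine,1,1,1,1,0
TT4_measured,1,0,1,0,1
Age,1,0,1,1,1
T4U_measured,1,0,1,1,1
Sex,1,1,1,0,1
query_hypothyroid,0,1,0,1,1
FTI_measured,1,1,1,1,0
I131_treatment,1,1,1,1,0
goitre,1,1,1,1,0
thyroid_surgery,1,0,0,0,0
query_hyperthyroid,1,0,0,1,0
tumor,0,1,0,0,0
sick,0,0,0,0,1
on_antithyroid_medication,1,0,0,0,0
psych,0,1,0,0,0
lithium,0,0,0,1,0
pregnant,1,0,1,0,0
query_on_thyroxine,0,1,0,0,1
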