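Feature,High,Medium,Low
TSH,23,4,3
T3_measured,22,5,3
on_thyroxine,7,19,4
TT4_measured,6,15,9
Age,4,14,12
T4U_measured,10,14,6
Sex,5,14,11
query_hypothyroid,8,12,10
FTI_measured,7,13,10
thyroid_surgery,5,7,18
query_hyperthyroid,6,7,17
I131_treatment,4,14,12
tumor,4,7,19
sick,4,3,23
on_antithyroid_medication,7,4,19
psych,5,2,23
lithium,2,3,25
goitre,5,14,11
pregnant,4,13,13
query_on_thyroxine,6,6,18
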