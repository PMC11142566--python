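Feature,XAI_Level,Expert_Level,XAI_Serial,Expert_Serial
TSH,High,High,1,1
T3_measured,High,High,2,2
on_thyroxine,Medium,Medium,3,4
TT4_measured,Medium,Medium,4,8
Age,Medium,Medium,5,9
T4U_measured,Medium,Medium,6,3
Sex,Medium,Medium,7,7
query_hypothyroid,Medium,Medium,8,5
FTI_measured,Medium,Medium,9,6
thyroid_surgery,Low,Low,10,15
query_hyperthyroid,Low,Low,11,13
I131_treatment,Low,Medium,12,11
tumor,Low,Low,13,17
sick,Low,Low,14,20
on_antithyroid_medication,Low,Low,15,16
psych,Low,Low,16,19
lithium,Low,Low,17,18
goitre,Low,Medium,18,10
pregnant,Low,Low,19,12
query_on_thyroxine,Low,Low,20,14
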