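patient_id,episode,day
200453,Myocardial infarction,572
200453,Congestive heart failure,2064
200453,Congestive heart failure,2562
200453,Myocardial infarction,2562
200453,Congestive heart failure,2593
201195,Congestive heart failure,1343
201195,Congestive heart failure,1426
201195,Angina,3086
201195,Congestive heart failure,3086
201195,Myocardial infarction,3086
201195,Congestive heart failure,3143
201195,Congestive heart failure,3183
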