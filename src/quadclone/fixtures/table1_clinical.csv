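case,age,histology,stage,lymph_nodes,regression_pct,hpv_type,survival_months,survival_censored,cause_of_death
CE01-01,45,SCC,IIb,Neg,76,16,60,T,
CE01-02,33,SCC,IIb,Neg,77,6;45,20,F,Local recurrence
CE01-03,49,Adeno,Ib2,ND,88,Neg,7,F,Local recurrence
CE01-04,55,SCC,IIb,ND,,Neg,6,F,Local recurrence
CE01-06,55,SCC,IIb,ND,57,16,56,T,
CE01-09,33,SCC,IIIb,Pos,41,ND,7,F,Local recurrence
CE01-10,30,SCC,IIb,Neg,100,18,51,T,
CE01-12,67,SCC,IIb,Pos,67,16,50,T,
CE01-13,48,Adeno,IIb,Neg,36,18,8,F,Liver metastasis
CE01-14,27,SCC,IIb,Neg,81,16,41,T,
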