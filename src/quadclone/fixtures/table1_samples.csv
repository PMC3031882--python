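case,week,quadrant,acgh_abnormal,tumour_pct
CE01-01,0,1,F,0
CE01-01,0,2,F,
CE01-01,0,3,F,0
CE01-01,0,4,T,
CE01-01,2,1,F,
CE01-01,2,2,F,
CE01-01,2,3,,
CE01-01,2,4,F,
CE01-01,5,1,F,
CE01-01,5,2,F,
CE01-01,5,3,F,1
CE01-01,5,4,F,<1
CE01-02,0,1,,
CE01-02,0,2,T,
CE01-02,0,3,T,85
CE01-02,0,4,T,
CE01-02,2,1,T,
CE01-02,2,2,T,10
CE01-02,2,3,T,40
CE01-02,2,4,T,
CE01-02,5,1,F,
CE01-02,5,2,F,
CE01-02,5,3,F,
CE01-02,5,4,,
CE01-03,0,1,,
CE01-03,0,2,F,10
CE01-03,0,3,F,0
CE01-03,0,4,F,30
CE01-03,2,1,,
CE01-03,2,2,F,
CE01-03,2,3,F,
CE01-03,2,4,F,
CE01-03,5,1,,
CE01-03,5,2,F,0
CE01-03,5,3,F,
CE01-03,5,4,F,<1
CE01-04,0,1,F,
CE01-04,0,2,F,
CE01-04,0,3,F,50
CE01-04,0,4,F,
CE01-04,2,1,,
CE01-04,2,2,F,
CE01-04,2,3,F,
CE01-04,2,4,F,
CE01-04,5,1,F,
CE01-04,5,2,F,0
CE01-04,5,3,F,
CE01-04,5,4,F,
CE01-06,0,1,F,
CE01-06,0,2,,
CE01-06,0,3,T,
CE01-06,0,4,F,
CE01-06,2,1,,
CE01-06,2,2,,
CE01-06,2,3,,
CE01-06,2,4,,
CE01-06,5,1,F,
CE01-06,5,2,,
CE01-06,5,3,F,
CE01-06,5,4,F,0
CE01-09,0,1,T,
CE01-09,0,2,,
CE01-09,0,3,T,
CE01-09,0,4,,
CE01-09,2,1,,
CE01-09,2,2,,
CE01-09,2,3,,
CE01-09,2,4,,
CE01-09,5,1,T,8
CE01-09,5,2,,
CE01-09,5,3,,
CE01-09,5,4,,
CE01-10,0,1,F,10
CE01-10,0,2,,
CE01-10,0,3,,
CE01-10,0,4,F,5
CE01-10,2,1,,
CE01-10,2,2,,
CE01-10,2,3,,
CE01-10,2,4,,
CE01-10,5,1,F,
CE01-10,5,2,,
CE01-10,5,3,,
CE01-10,5,4,F,
CE01-12,0,1,F,40
CE01-12,0,2,,
CE01-12,0,3,,
CE01-12,0,4,F,20
CE01-12,2,1,,
CE01-12,2,2,,
CE01-12,2,3,,
CE01-12,2,4,,
CE01-12,5,1,F,
CE01-12,5,2,,
CE01-12,5,3,,
CE01-12,5,4,F,5
CE01-13,0,1,T,40
CE01-13,0,2,T,
CE01-13,0,3,T,
CE01-13,0,4,T,
CE01-13,2,1,,
CE01-13,2,2,,
CE01-13,2,3,,
CE01-13,2,4,,
CE01-13,5,1,F,
CE01-13,5,2,T,
CE01-13,5,3,,
CE01-13,5,4,F,3
CE01-14,0,1,T,70
CE01-14,0,2,,
CE01-14,0,3,T,
CE01-14,0,4,,
CE01-14,2,1,,
CE01-14,2,2,,
CE01-14,2,3,,
CE01-14,2,4,,
CE01-14,5,1,F,
CE01-14,5,2,,
CE01-14,5,3,F,
CE01-14,5,4,,
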