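case,chrom,position,type,status,week0,week2,week5
CE01-02,1,108.1-119.9,Loss,Het,2;3,1;3;4,
CE01-02,1,q arm,Gain,Het,2;3,1;2;3;4,
CE01-02,3,55.8-cen,Loss,Het,2;3,1;2;3;4,
CE01-02,3,153.8-q tel,Gain,Hom,,,
CE01-02,4,86.6-q tel,Loss,Het,2;3;4,,
CE01-02,11,74.7-85.3,Gain,Het,3;4,,
CE01-02,11,85.3-q tel,Loss,Het,4,,
CE01-02,11,94.8-q tel,Loss,Het,2;3,1;2;3;4,
CE01-02,17,28.5-29.7,Amplicon,Het,2;3;4,,
CE01-02,17,34.9-35.3,Amplicon,Het,2;3;4,,
CE01-02,17,43.9-q tel,Gain,Het,4,,
CE01-02,17,47.0-q tel,Gain,Het,,4,
CE01-02,17,Whole chr,Gain,Het,2;3,1,
CE01-02,19,p tel-14.5,Gain,Het,,1;2,
CE01-02,19,9.5-14.5,Gain,Het,3;4,,
CE01-02,19,Whole chr,Loss,Het,,3;4,
CE01-02,X,Whole chr,Gain,Het,2;3,1,
CE01-13,3,141.6-q tel,Gain,Hom,,,
CE01-13,4,167.4-170.1,Loss,Hom,,,
CE01-13,9,p tel-13.2,Loss,Hom,,,
CE01-13,10,Whole chr,Gain,Het,1;2,,
CE01-13,15,25.0-80.7,Loss,Het,3,,2
CE01-13,15,25.0-45.7,Loss,Het,1;2;4,,
CE01-13,15,45.7-46.2,Gain,Het,1;2;4,,
CE01-13,15,46.2-60.7,Loss,Het,1;2;4,,
CE01-13,15,60.7-77.7,Gain,Het,1;2,,
CE01-13,15,60.7-61.7,Gain,Het,4,,
CE01-13,15,75.9-77.7,Gain,Het,4,,
CE01-13,15,77.7-77.9,Loss,Het,1;2;4,,
CE01-13,15,77.9-78.1,Gain,Het,1;2;4,,
CE01-13,15,78.1-81.0,Loss,Het,1;2;4,,
CE01-13,15,81.0-89.3,Gain,Het,1;2;4,,
CE01-13,15,89.3-q tel,Loss,Hom,,,
CE01-13,16,cen-q tel,Loss,Het,3;4,,2
CE01-13,18,23.2-q tel,Loss,Het,3;4,,2
CE01-13,19,p tel-cen,Gain,Het,1;2,,
CE01-13,19,cen-51.5,Further gain,Het,1;2,,
CE01-13,19,cen-q tel,Gain,Het,3;4,,2
CE01-13,20,20.5-22.1,Loss,Het,3;4,,2
CE01-13,X,65.0-q tel,Loss,Het,3;4,,2
CE01-09,2,p tel-180.6,Gain,Het,3,,
CE01-09,5,p tel-5.1,Gain,Het,3,,
CE01-09,5,5.1-cen,Further gain,Het,3,,
CE01-09,5,cen-q tel,Loss,Het,3,,
CE01-09,6,p tel-35.6,Gain,Het,3,,
CE01-09,7,p tel-2.3,Gain,Het,3,,
CE01-09,7,2.3-cen,Loss,Het,3,,
CE01-09,8,Whole chr,Gain,Het,3,,
CE01-09,10,p tel-27.8,Loss,Het,3,,
CE01-09,10,87.3-q tel,Loss,Het,3,,
CE01-09,11,75.1-98.9,Gain,Hom,,,
CE01-09,11,98.9-104.4,Further gain,Hom,,,
CE01-09,11,104.4-q tel,Loss,Hom,,,
CE01-09,16,p tel-cen,Loss,Het,3,,
CE01-09,16,80.3-q tel,Gain,Het,3,,
CE01-09,18,Whole chr,Loss,Het,3,,
CE01-09,19,p tel-cen,Loss,Het,3,,
CE01-09,19,Whole chr,Loss,Het,1,,1
CE01-09,21,p tel-33.5,Loss,Het,3,,
CE01-09,22,Whole chr,Loss,Het,3,,
CE01-09,X,Whole chr,Gain,Het,3,,
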