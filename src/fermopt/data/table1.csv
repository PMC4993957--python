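Glu,Mal,Mann,CP,Yeast,CS,SC,FS,VB1,TF
25,25,20,12.5,12.5,5,0.5,12.5,1.5,1240
20,25,25,10,12.5,6.25,0.5,10,1.5,880
25,20,25,12.5,10,6.25,0.625,12.5,1.5,980
20,25,25,12.5,10,5,0.625,12.5,1.5,950
25,25,20,10,10,5,0.625,10,1.875,800
25,25,25,10,10,6.25,0.5,10,1.875,760
20,20,20,10,10,5,0.5,10,1.5,740
25,20,20,10,12.5,5,0.5,10,1.5,740
20,20,20,12.5,10,6.25,0.5,12.5,1.875,850
20,20,25,10,12.5,5,0.625,10,1.875,850
20,25,20,12.5,12.5,6.25,0.625,12.5,1.875,990
25,20,25,12.5,12.5,5,0.5,12.5,1.875,1030
20,20,20,10,10,5,0.5,12.5,1.5,1520
20,20,20,12.8,12,5,0.5,10,1.5,990
20,20,20,10,10,5,0.5,12.5,1.5,1510
20,20,20,10,7.2,5,0.5,12.5,1.5,1360
20,20,20,10,12.8,5,0.5,10,1.5,890
20,20,20,7.2,10,5,0.5,10,1.5,1320
20,20,20,12,12,5,0.5,10,1.5,1420
20,20,20,10,10,5,0.5,10,1.5,1560
20,20,20,12,8,5,0.5,12.5,1.5,1510
20,20,20,8,12,5,0.5,10,1.5,1080
20,20,20,10,10,5,0.5,12.5,1.5,1500
20,20,20,8,8,5,0.5,12.5,1.5,1610
20,20,20,10,10,5,0.5,25,1.5,1310
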