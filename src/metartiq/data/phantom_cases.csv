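case_id,kvp,iq,kernel,imar,vmi,slice_mm,diff_hu,sd_artifact,bloom_vol,amplitude_low_freq,cv,q1,q2,q3,q4,q5,q6,vg_sum
1,120,80,Bv40f,ExtremityImplants,110,0.4,-86,50,61.6,42723.6,5.4,5,1,1,2,3,3,15
2,120,80,Bv40f,HipImplants,110,0.4,-66,67,61.2,43578.6,2.3,4,1,3,2,3,4,17
3,120,80,Bv40f,ThoracicCoils,110,0.4,-131,141,61.7,44911.3,3.9,2,1,2,0,0,2,7
4,120,80,Bv40f,None,110,0.4,-213,128,62.6,40267.9,13.8,1,4,0,0,3,4,12
5,120,80,Bv40f,Pacemaker,110,0.4,-134,107,61.6,38909.2,6.6,3,2,3,2,3,4,17
6,120,100,Qr40f,Pacemaker,110,0.4,-119,151,59.9,44501.0,11.0,3,2,3,2,4,3,17
7,140,55,Qr40f,Pacemaker,110,0.4,-99,99,59.1,52724.3,9.5,4,5,3,1,4,1,18
8,140,60,Qr40f,Pacemaker,110,0.4,-51,140,58.5,38961.9,3.4,5,4,3,1,4,5,22
9,120,55,Qr40f,Pacemaker,110,0.4,-137,168,61.3,52770.9,4.0,3,2,3,1,4,5,18
10,120,60,Qr40f,Pacemaker,110,0.4,-108,150,60.0,39782.8,5.3,3,2,3,2,4,4,18
11,120,80,Bl56f,Pacemaker,110,0.4,-45,145,42.3,52021.7,3.5,4,3,2,1,2,1,13
12,120,80,Bv36f,Pacemaker,110,0.4,-115,133,62.7,46673.0,13.0,4,3,3,1,3,4,18
13,120,80,Bv40f,Pacemaker,110,0.4,-72,120,61.8,41604.8,4.3,2,3,3,2,3,4,17
14,120,80,Bv44f,Pacemaker,110,0.4,-103,108,61.2,42936.0,1.6,4,2,3,1,3,4,17
15,120,80,Bv56f,Pacemaker,110,0.4,-99,138,56.0,44470.7,5.7,3,1,1,0,2,2,9
16,120,80,Qr36f,Pacemaker,110,0.4,-133,123,60.6,42913.5,2.2,4,4,3,1,3,3,18
17,120,80,Qr40f,Pacemaker,110,0.4,-115,118,60.2,43677.7,1.8,2,4,4,3,4,3,20
18,120,80,Qr44f,Pacemaker,110,0.4,-132,126,58.5,43448.0,3.8,3,4,3,1,4,3,18
19,120,80,Qr40f,Pacemaker,40,0.4,-109,207,89.8,37437.5,5.4,0,2,1,0,1,0,4
20,120,80,Qr40f,Pacemaker,62,0.4,-86,134,84.6,39828.3,5.7,0,4,1,0,3,3,11
21,120,80,Qr40f,Pacemaker,190,0.4,-108,158,52.6,47422.1,1.1,2,2,3,1,2,3,13
22,120,80,Bv40f,None,70,1,-150,165,80.0,38917.6,0.8,2,4,3,2,5,5,21
23,120,80,Qr40f,None,70,1,-143,170,,40270.2,1.3,3,5,1,2,3,3,17
24,120,80,Qr40f,None,T3D,0.4,46,211,83.3,43657.8,3.0,0,1,1,1,4,3,10
25,140,80,Qr40f,Pacemaker,40,0.4,-273,275,92.7,45531.2,7.0,0,3,0,0,1,1,5
26,140,80,Qr40f,Pacemaker,67,0.4,-141,143,81.5,46290.3,7.0,1,3,0,0,1,1,6
27,140,80,Qr40f,Pacemaker,110,0.4,-121,96,59.6,56096.3,5.5,3,4,3,1,3,3,17
28,140,80,Qr40f,Pacemaker,T3D,0.4,-142,129,75.0,55114.1,3.4,3,6,3,3,5,3,23
29,90,80,Qr40f,Pacemaker,110,0.4,-14,147,65.2,45112.8,2.2,1,0,3,0,2,1,7
30,90,80,Qr40f,Pacemaker,T3D,0.4,-170,199,85.0,45160.2,7.1,0,4,1,0,2,1,8
31,120,80,Bv40f,Pacemaker,T3D,0.4,-140,141,79.0,49692.4,3.0,3,5,3,1,4,3,19
32,120,80,Qr40f,Pacemaker,110,0.4,-39,137,60.3,48914.2,1.5,3,4,3,1,4,4,19
33,120,80,Qr40f,Pacemaker,110,1,-123,108,60.3,50246.3,2.4,3,5,3,3,3,3,20
34,120,80,Qr40f,Pacemaker,110,3,-136,108,61.8,48888.0,3.7,5,4,6,2,5,3,25
35,140,80,Qr40f,Pacemaker,110,1,-97,89,59.4,51022.6,2.7,4,5,3,3,4,3,22
36,140,80,Qr40f,Pacemaker,110,3,-140,81,60.8,51012.5,5.4,5,5,3,3,5,4,25
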