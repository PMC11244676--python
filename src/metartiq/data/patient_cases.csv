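case_id,kvp,iq,kernel,imar,vmi,slice_mm,diff_hu,sd_artifact,bloom_vol,amplitude_low_freq,cv,q1,q2,q3,q4,q5,q6,vg_sum
1,120,80,Qr40f,Pacemaker,40,0.4,776,187,96.3,69478.9,12.4,0,0,0,0,1,0,1
2,120,80,Qr40f,Pacemaker,62,0.4,396,121,73.5,37266.1,1.5,0,0,0,0,0,0,0
3,120,80,Qr40f,Pacemaker,T3D,0.4,331,75,54.7,23155.9,1.1,1,0,1,0,3,4,9
4,120,80,Qr40f,Pacemaker,SPP-70,0.4,446,113,62.5,40961.9,11.4,0,0,0,0,3,0,3
5,120,80,Qr40f,Pacemaker,90,0.4,308,59,49.1,26209.7,2.6,0,0,0,0,2,1,3
6,120,80,Bv56f,Pacemaker,90,0.4,428,104,46.4,45695.2,9.4,0,0,0,0,3,1,4
7,120,80,Qr40f,Pacemaker,190,0.4,304,80,35.3,35855.6,5.2,0,0,0,0,2,2,4
8,120,80,Qr36f,Pacemaker,110,0.4,339,137,43.2,21071.3,19.1,1,0,0,0,4,2,7
9,120,80,Qr40f,Pacemaker,110,0.4,268,77,42.8,18676.3,14.1,0,0,0,0,3,1,4
10,120,80,Qr44f,Pacemaker,110,0.4,360,75,42.4,31958.9,14.1,1,0,0,0,3,1,5
11,120,80,Qr56f,Pacemaker,110,0.4,397,104,40.2,40797.9,11.7,0,0,0,0,2,2,4
12,120,80,Bl56f,Pacemaker,110,0.4,355,102,37.2,51823.4,13.8,2,0,0,0,3,2,7
13,120,80,Bv36f,Pacemaker,110,0.4,350,134,43.5,22780.7,10.3,0,0,0,0,2,1,3
14,120,80,Bv40f,Pacemaker,110,0.4,286,58,43.1,21459.0,16.8,0,0,0,0,4,2,6
15,120,80,Bv44f,Pacemaker,110,0.4,340,70,42.8,39596.0,9.8,0,0,0,0,2,2,4
16,120,80,Bv56f,Pacemaker,110,0.4,373,88,40.6,44783.1,14.0,0,0,0,0,0,0,0
17,120,80,Qr40f,None,110,0.4,86,37,42.9,37359.9,4.9,0,0,0,0,3,0,3
18,120,80,Qr40f,ThoracicCoils,110,0.4,211,94,42.8,15596.6,22.8,1,1,1,2,5,1,11
19,120,80,Qr40f,ExtremityImplants,110,0.4,416,106,42.8,17471.6,13.3,1,0,1,1,4,3,10
20,120,80,Qr40f,HipImplants,110,0.4,398,108,42.8,16930.1,17.9,1,0,1,1,4,4,11
21,120,80,Bv56f,ThoracicCoils,110,0.4,127,64,40.6,57752.4,12.3,0,0,0,0,4,1,5
22,120,80,Bv56f,Pacemaker,110,1,411,98,34.4,39611.4,12.3,0,0,1,1,5,3,10
23,120,80,Qr40f,Pacemaker,110,1,277,77,36.3,17451.3,3.2,1,0,0,0,4,2,7
24,120,80,Bv56f,Pacemaker,110,3,317,89,27.0,29432.3,32.6,1,0,1,2,4,3,11
25,120,80,Qr40f,Pacemaker,110,3,264,75,28.7,15987.0,26.2,0,0,0,1,5,1,7
26,120,80,Bv56f,Pacemaker,T3D,0.8,321,101,50.1,35135.6,5.0,2,2,2,1,5,2,14
27,120,80,Bv56f,Pacemaker,T3D,3,342,102,37.1,28447.4,19.9,2,2,2,1,4,3,14
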