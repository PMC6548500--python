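footprint_id,side,Dt1_BL,Dt2_BL,Dt3_BL,Dt4_BL,Dt5_BL,mtm_BL,mtl_BL,ntu_BL,mttu_BL,ccm_BL,ctul_BL,mtm_horiz,mttu_horiz,ctul_horiz,T1_T5,max_FL,max_FW,Aa,FI_printed,stature_printed,mass_a_printed,mass_b_printed,mass_c_printed,morphotype,in_summary
SM3,R,13,12.3,,,,10.5,9.2,5.5,6.8,2.3,2.4,5.5,4.7,4.3,,13,6,20,0.46,84.36,11.78,,,1,1
SM4,L,13.5,12.5,11.5,11,9.8,10.2,8,4,5.5,2.2,1.6,5.5,4,4.2,40,13.5,6.5,22,0.48,87.61,12.55,,,1,1
SM43,L,13.5,13.5,,,,10.5,9.4,5.5,6.5,2.2,1.8,6,5.5,4.6,,13.5,6.5,20,0.48,87.61,12.55,,,1,1
SM17,R,14.2,13.8,13.5,12.6,10.8,10.2,8.5,5,6,2,1.8,6.5,4.8,4,32,14.2,6.8,25,0.48,92.15,13.70,,,1,1
SM5,R,17,16.8,15.5,14,13,12,12,,,2.5,2,6.5,,5,35,17,6.8,28,0.40,110.32,19.50,,,2,1
SM42,R,17,16.8,,,,12.5,11.5,,10,3.4,2.5,7,,5.4,,17,7.2,25,0.42,110.32,19.50,,,2,1
SM26,R,18,16.5,15,14,,,,,,2,3,,,5,,18,,28,,116.81,22.12,,,2,0
CA8,R,20.2,19.8,19.4,18.3,16.8,15,13,7.5,9.2,2.6,2,7.5,6,4.5,30,20.2,8,,0.40,131.08,29.18,,,3,1
C10,R,20.5,,19.2,18.4,16.5,15.5,12.5,6.5,8.5,2.8,2.6,7,5.5,5.6,32,20.5,8,,0.39,133.03,30.30,,,3,1
SM15,L,20.5,20.5,18.5,17.5,16,15.4,13,6.5,7.8,4,2,7,4,6,30,20.5,7,45,0.34,133.03,30.30,,,3,1
SM11,R,21,20.2,19.7,18,16.8,15.4,14.5,5.5,8,3.3,2.3,7.5,6.8,6,30,21,7.5,40,0.36,136.28,32.28,,,3,1
SM6,L,21,21.5,20.5,18.8,17,17.5,15.5,6.8,8.5,4,2.2,9.2,5.5,5.7,20,21.5,9,40,0.42,139.52,34.38,,,3,1
SM1,L,21.2,21.3,20.8,20.4,18.5,17.4,14.8,6.8,8.7,3.8,2.5,8,5,6,20,21.3,8.5,40,0.40,138.22,33.52,,,3,1
C33,L,22.2,21,19.5,17.3,14.8,15.5,10.7,6,7.8,2.5,2,10,6.5,5.8,45,22.2,10.5,48,0.47,144.06,37.55,,,3,0
C36,L,22.7,21.7,19.5,17.8,16.2,,14.5,,,3,2.5,,,5.5,48,22.7,,,,147.31,39.99,,,3,0
CA1,R,22.4,21.8,20.8,18.5,,14.8,12.8,7,,3.1,,8,,,,22.4,8.5,,0.38,145.36,,45.48,46.66,4,1
CA2,L,22.5,22,21,20,18.5,17.3,15.2,6,8.6,3.5,3.5,8.8,6,6.4,30,22.5,8.5,44,0.38,146.01,,45.66,47.19,4,1
C61,L,23,21.7,20.8,20,19.5,16.4,14,8.5,9.5,3.8,3,7.5,6.5,5.4,30,23,9,45,0.39,149.25,,46.57,49.82,4,1
C63,R,23.3,22.2,20.8,19.8,18.7,17,14,7.9,9.5,3.5,3.8,8.5,6.7,5.3,32,23.3,9,42,0.39,151.20,,47.12,51.39,4,1
M21,R,,21.6,21.3,20.7,19.2,16.7,14.6,7.8,10.5,3.5,2.4,9.6,4.8,6.2,,,9.8,42,,,,,,4,0
C9,R,22.5,,,,,,,,,,,8,,5.5,,22.5,8,,0.36,146.01,,45.66,47.19,4,0
C44b,L,21.5,21,20,19.5,18.5,15,13,7,4,2.2,1.5,10,5,5.5,20,21.5,10.5,50,0.49,139.52,,43.84,41.93,4,0
C60,L,25.3,24.2,22.7,21.4,20,18,14.8,6,8,3.5,3.3,10.5,7.5,6.4,35,25.3,11,52,0.43,164.18,,50.76,,5,1
C37,L,25.7,23.8,22.5,21,19.5,18.4,14.7,6,7.8,3.7,3.5,10.5,7.5,7,35,25.7,10.5,55,0.41,166.77,,51.48,,5,1
C35b,R,26.2,24.8,22.8,20.7,18.7,17,13.7,5.8,7.2,3.7,2.7,9.5,7,6.7,40,26.2,10.5,,0.40,170.02,,52.39,,5,1
C44,L,25,23.5,22.5,20.8,19,16.8,14.2,5.5,6.7,2.8,2,9.2,5.7,6,45,25,10,50,0.40,162.23,,50.21,,5,0
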