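footprint_id,in_situ,cast_1950,Dt1_BL,Dt2_BL,Dt3_BL,mtm_BL,mtl_BL,ccm_BL,ctul_BL,mtm_horiz,ctul_horiz
SM3,1,0,13,12.3,,10.5,9.2,2.3,2.4,5.5,4.3
SM4,1,0,13.5,12.5,11.5,10.2,8,2.2,1.6,5.5,4.2
SM43,1,0,13.5,13.5,,10.5,9.4,2.2,1.8,6,4.6
SM17,1,0,14.2,13.8,13.5,10.2,8.5,2,1.8,6.5,4
SM5,1,0,17,16.8,15.5,12,12,2.5,2,6.5,5
SM42,1,0,17,16.8,,12.5,11.5,3.4,2.5,7,5.4
SM26,1,0,18,16.5,15,,,2,3,,5
CA8,1,1,20.2,19.8,19.4,15,13,2.6,2,7.5,4.5
C10,1,0,20.5,,19.2,15.5,12.5,2.8,2.6,7,5.6
SM15,1,0,20.5,20.5,18.5,15.4,13,4,2,7,6
SM11,1,0,21,20.2,19.7,15.4,14.5,3.3,2.3,7.5,6
SM6,1,0,21,21.5,20.5,17.5,15.5,4,2.2,9.2,5.7
SM1,1,1,21.2,21.3,20.8,17.4,14.8,3.8,2.5,8,6
C33,1,1,22.2,21,19.5,15.5,10.7,2.5,2,10,5.8
C36,1,1,22.7,21.7,19.5,,14.5,3,2.5,,5.5
M21,0,1,,21.6,21.3,16.7,14.6,3.5,2.4,9.6,6.2
CA1,1,1,22.4,21.8,20.8,14.8,12.8,3.1,,8,
CA2,1,0,22.5,22,21,17.3,15.2,3.5,3.5,8.8,6.4
C61,1,1,23,21.7,20.8,16.4,14,3.8,3,7.5,5.4
C63,1,1,23.3,22.2,20.8,17,14,3.5,3.8,8.5,5.3
C60,1,1,25.3,24.2,22.7,18,14.8,3.5,3.3,10.5,6.4
C37,1,1,25.7,23.8,22.5,18.4,14.7,3.7,3.5,10.5,7
C35b,1,1,26.2,24.8,22.8,17,13.7,3.7,2.7,9.5,6.7
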