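site,diagnosis,n_male,n_female,age_mean,age_sd
OSK,HC,126,114,35.0,16.4
OSK,SZ,29,38,35.3,12.9
OSK,MDD,2,6,53.3,13.2
OSK,ASD,10,4,27.4,7.2
KYS,HC,43,34,34.0,9.3
KYS,SZ,38,31,36.3,12.5
KYS,BD,10,6,43.4,9.3
KYS,MDD,10,12,45.6,11.8
KYS,ASD,8,0,34.1,8.2
NCNP,HC,24,42,42.5,14.2
NCNP,SZ,13,28,35.8,14.4
NCNP,MDD,4,1,36.0,10.6
NCNP,ASD,3,2,26.4,4.3
UTH,HC,26,35,38.2,8.2
UTH,SZ,16,11,31.3,10.0
UTH,BD,2,1,38.3,15.0
UTH,MDD,4,1,37.8,8.6
UTH,ASD,5,4,28.9,9.5
NGY,HC,27,27,40.0,16.1
NGY,SZ,5,16,43.0,8.5
NGY,BD,6,7,51.5,14.6
NGY,MDD,1,2,53.7,10.7
NGY,ASD,14,0,32.2,10.1
NARA,HC,27,18,26.0,4.8
NARA,SZ,0,2,29.5,10.6
NARA,ASD,61,21,28.3,8.1
HKK,HC,6,1,33.4,2.6
HKK,SZ,5,6,26.5,8.2
HKK,BD,5,4,43.8,15.5
HKK,MDD,3,4,54.1,17.0
HKK,ASD,0,1,13.0,0.0
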