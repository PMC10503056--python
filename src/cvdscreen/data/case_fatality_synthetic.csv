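condition,sex,age_lo,fraction
chd,female,30,0.1380
chd,female,35,0.1656
chd,female,40,0.1932
chd,female,45,0.2208
chd,female,50,0.2484
chd,female,55,0.2760
chd,female,60,0.3036
chd,female,65,0.3312
chd,female,70,0.3588
chd,female,75,0.3864
chd,female,80,0.4140
chd,female,85,0.4416
chd,female,90,0.4692
chd,female,95,0.4968
chd,male,30,0.1500
chd,male,35,0.1800
chd,male,40,0.2100
chd,male,45,0.2400
chd,male,50,0.2700
chd,male,55,0.3000
chd,male,60,0.3300
chd,male,65,0.3600
chd,male,70,0.3900
chd,male,75,0.4200
chd,male,80,0.4500
chd,male,85,0.4800
chd,male,90,0.5100
chd,male,95,0.5400
stroke,female,30,0.1840
stroke,female,35,0.2070
stroke,female,40,0.2300
stroke,female,45,0.2530
stroke,female,50,0.2760
stroke,female,55,0.2990
stroke,female,60,0.3220
stroke,female,65,0.3450
stroke,female,70,0.3680
stroke,female,75,0.3910
stroke,female,80,0.4140
stroke,female,85,0.4370
stroke,female,90,0.4600
stroke,female,95,0.4830
stroke,male,30,0.2000
stroke,male,35,0.2250
stroke,male,40,0.2500
stroke,male,45,0.2750
stroke,male,50,0.3000
stroke,male,55,0.3250
stroke,male,60,0.3500
stroke,male,65,0.3750
stroke,male,70,0.4000
stroke,male,75,0.4250
stroke,male,80,0.4500
stroke,male,85,0.4750
stroke,male,90,0.5000
stroke,male,95,0.5250
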