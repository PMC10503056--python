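sex,age,q
female,18,0.000917
female,19,0.000929
female,20,0.000941
female,21,0.000955
female,22,0.000970
female,23,0.000987
female,24,0.001005
female,25,0.001025
female,26,0.001047
female,27,0.001071
female,28,0.001097
female,29,0.001126
female,30,0.001158
female,31,0.001193
female,32,0.001231
female,33,0.001273
female,34,0.001320
female,35,0.001370
female,36,0.001426
female,37,0.001487
female,38,0.001554
female,39,0.001627
female,40,0.001708
female,41,0.001796
female,42,0.001893
female,43,0.002000
female,44,0.002117
female,45,0.002245
female,46,0.002386
female,47,0.002541
female,48,0.002710
female,49,0.002897
female,50,0.003101
female,51,0.003325
female,52,0.003571
female,53,0.003841
female,54,0.004138
female,55,0.004463
female,56,0.004820
female,57,0.005212
female,58,0.005642
female,59,0.006114
female,60,0.006632
female,61,0.007200
female,62,0.007824
female,63,0.008508
female,64,0.009259
female,65,0.010084
female,66,0.010989
female,67,0.011982
female,68,0.013072
female,69,0.014268
female,70,0.015580
female,71,0.017021
female,72,0.018602
female,73,0.020337
female,74,0.022241
female,75,0.024330
female,76,0.026624
female,77,0.029140
female,78,0.031902
female,79,0.034934
female,80,0.038261
female,81,0.041911
female,82,0.045918
female,83,0.050316
female,84,0.055141
female,85,0.060438
female,86,0.066250
female,87,0.072629
female,88,0.079629
female,89,0.087312
female,90,0.095744
female,91,0.104997
female,92,0.115153
female,93,0.126298
female,94,0.138529
female,95,0.151952
female,96,0.166684
female,97,0.182851
female,98,0.200594
female,99,0.220066
female,100,0.241436
male,18,0.001238
male,19,0.001254
male,20,0.001271
male,21,0.001289
male,22,0.001310
male,23,0.001332
male,24,0.001357
male,25,0.001384
male,26,0.001413
male,27,0.001446
male,28,0.001481
male,29,0.001521
male,30,0.001564
male,31,0.001611
male,32,0.001662
male,33,0.001719
male,34,0.001781
male,35,0.001850
male,36,0.001925
male,37,0.002007
male,38,0.002098
male,39,0.002197
male,40,0.002306
male,41,0.002425
male,42,0.002556
male,43,0.002700
male,44,0.002858
male,45,0.003031
male,46,0.003221
male,47,0.003430
male,48,0.003659
male,49,0.003910
male,50,0.004186
male,51,0.004489
male,52,0.004821
male,53,0.005186
male,54,0.005586
male,55,0.006025
male,56,0.006507
male,57,0.007036
male,58,0.007616
male,59,0.008253
male,60,0.008953
male,61,0.009720
male,62,0.010562
male,63,0.011486
male,64,0.012500
male,65,0.013613
male,66,0.014835
male,67,0.016175
male,68,0.017647
male,69,0.019261
male,70,0.021033
male,71,0.022978
male,72,0.025112
male,73,0.027454
male,74,0.030025
male,75,0.032846
male,76,0.035942
male,77,0.039339
male,78,0.043068
male,79,0.047161
male,80,0.051652
male,81,0.056580
male,82,0.061990
male,83,0.067926
male,84,0.074441
male,85,0.081591
male,86,0.089438
male,87,0.098049
male,88,0.107500
male,89,0.117872
male,90,0.129254
male,91,0.141746
male,92,0.155456
male,93,0.170502
male,94,0.187014
male,95,0.205135
male,96,0.225023
male,97,0.246849
male,98,0.270802
male,99,0.297090
male,100,0.325939
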