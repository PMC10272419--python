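wavelength_nm,mua_per_cm
1000,0.363
1010,0.281958
1020,0.227167
1030,0.190635
1040,0.167329
1050,0.154264
1060,0.15
1070,0.152755
1080,0.160452
1090,0.172418
1100,0.188
1110,0.224959
1120,0.304683
1130,0.431457
1140,0.590089
1150,0.72
1160,0.805445
1170,0.89054
1180,0.965805
1190,1.01964
1200,1.04
1210,1.02448
1220,0.988396
1230,0.946989
1240,0.913635
1250,0.9
1260,0.913463
1270,0.951248
1280,1.01027
1290,1.08769
1300,1.18
1310,1.31928
1320,1.54693
1330,1.87684
1340,2.32464
1350,2.9
1360,3.73573
1370,5.03762
1380,6.89866
1390,9.30703
1400,12
1410,14.7699
1420,17.7619
1430,21
1440,25.2449
1450,28
1460,27.5322
1470,26.399
1480,25
1490,22.9529
1500,20.5
1510,18.113
1520,15.7397
1530,13.609
1540,11.8451
1550,10.5
1560,9.43142
1570,8.50313
1580,7.73347
1590,7.13093
1600,6.7
1610,6.39226
1620,6.14352
1630,5.93748
1640,5.76032
1650,5.6
1660,5.45086
1670,5.31528
1680,5.1943
1690,5.0889
1700,5
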