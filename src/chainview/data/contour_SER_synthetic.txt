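# synthetic rotamericity contour grid
# residue: SER
# origins: -180.0
# spacings: 10.0
# sizes: 36
-180.0 16.2238
-170.0 8.8361
-160.0 4.6319
-150.0 3.4195
-140.0 5.7199
-130.0 12.4653
-120.0 23.2732
-110.0 34.4339
-100.0 39.9465
-90.0 36.2812
-80.0 25.7927
-70.0 14.3518
-60.0 6.2504
-50.0 2.1306
-40.0 0.5684
-30.0 0.1187
-20.0 0.0194
-10.0 0.0025
0.0 0.0003
10.0 0.0002
20.0 0.0011
30.0 0.0057
40.0 0.0256
50.0 0.0998
60.0 0.3387
80.0 2.6840
90.0 6.5799
100.0 15.1149
110.0 31.3515
130.0 74.0575
140.0 77.4606
150.0 63.7588
160.0 44.0785
170.0 27.6135
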