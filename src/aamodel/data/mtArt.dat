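0.2
0.2 0.2
1 4 500
254 36 98 11
0.2 154.0 262.0 0.2 0.2
0.2 0.2 183.0 862.0 0.2 262.0
200.0 0.2 121.0 12.0 81.0 3.0 44.0
0.2 41.0 180.0 0.2 12.0 314.0 15.0 0.2
26.0 2.0 21.0 7.0 63.0 11.0 7.0 3.0 0.2
4 2 13 1 79 16 2 1 6 515
0.2 209.0 467.0 2.0 0.2 349.0 106.0 0.2 0.2 3.0 4.0
121.0 5.0 79.0 0.2 312.0 67.0 0.2 56.0 0.2 515.0 885.0 106.0
13.0 5.0 20.0 0.2 184.0 0.2 0.2 1.0 14.0 118.0 263.0 11.0 322.0
49.0 0.2 17.0 0.2 0.2 39.0 8.0 0.2 1.0 0.2 12.0 17.0 5.0 15.0
673 3 398 44 664 52 31 226 11 7 8 144 112 36 87
244.0 0.2 166.0 0.2 183.0 44.0 43.0 0.2 19.0 204.0 48.0 70.0 289.0 14.0 47.0 660.0
0.2 0.2 8.0 0.2 22.0 7.0 11.0 2.0 0.2 0.2 21.0 16.0 71.0 54.0 0.2 2.0 0.2
1.0 4.0 251.0 0.2 72.0 87.0 8.0 9.0 191.0 12.0 20.0 117.0 71.0 792.0 18.0 30.0 46.0 38.0
340.0 0.2 23.0 0.2 350.0 0.2 14.0 3.0 0.2 1855.0 85.0 26.0 281.0 52.0 32.0 61.0 544.0 0.2 2.0

0.054116 0.018227 0.039903 0.020160 0.009709 0.018781 0.024289 0.068183 0.024518 0.092638 0.148658 0.021718 0.061453 0.088668 0.041826 0.091030 0.049194 0.029786 0.039443 0.057700
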