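3.3
1.7 33.6
16.1 3.2 617.0
272.5 61.1 94.6 9.5
7.3 231.0 190.3 19.3 49.1
17.1 6.4 174.0 883.6 3.4 349.4
289.3 7.2 99.3 26.0 82.4 8.9 43.1
2.3 61.7 228.9 55.6 37.5 421.8 14.9 7.4
33.2 0.2 24.3 1.5 48.8 0.2 7.3 3.4 1.6
15.6 4.1 7.9 0.5 59.7 23.0 1.0 3.5 6.6 425.2
0.2 292.3 413.4 0.2 0.2 334.0 163.2 10.1 23.9 8.4 6.7
136.5 3.8 73.7 0.2 264.8 83.9 0.2 52.2 7.1 449.7 636.3 83.0
26.5 0.2 12.9 2.0 167.8 9.5 0.2 5.8 13.1 90.3 234.2 16.3 215.6
61.8 7.5 22.6 0.2 8.1 52.2 20.6 1.3 15.6 2.6 11.4 24.3 5.4 10.5
644.9 11.8 420.2 51.4 656.3 96.4 38.4 257.1 23.1 7.2 15.2 144.9 95.3 32.2 79.7
378.1 3.2 184.6 2.3 199.0 39.4 34.5 5.2 19.4 222.3 50.0 75.5 305.1 19.3 56.9 666.3
3.1 16.9 6.4 0.2 36.1 6.1 3.5 12.3 4.5 9.7 27.2 6.6 48.7 58.2 1.3 10.3 3.6
2.1 13.8 141.6 13.9 76.7 52.3 10.0 4.3 266.5 13.1 5.7 45.0 41.4 590.5 4.2 29.7 29.0 79.8
321.9 5.1 7.1 3.7 243.8 9.0 16.3 23.7 0.3 1710.6 126.1 11.1 279.6 59.6 17.9 49.5 396.4 13.7 15.6

0.06887993 0.02103698 0.03038997 0.02069598 0.00996599 0.01862298 0.02498898 0.07196793 0.02681397 0.08507191 0.15671684 0.01927598 0.05065195 0.08171192 0.04480296 0.08053492 0.05638594 0.02799797 0.03740396 0.06608293
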