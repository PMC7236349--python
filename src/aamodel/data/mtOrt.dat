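0.04
0.03 0.22
0.14 0.09 6.01
0.64 1.63 0.57 0.24
0.09 3.01 1.44 0.30 0.25
0.20 0.03 1.64 10.55 0.25 2.50
1.05 0.21 0.69 1.13 1.25 0.08 1.24
0.07 1.43 2.55 0.46 0.24 5.73 0.12 0.08
0.08 0.04 0.44 0.05 0.28 0.05 0.06 0.04 0.10
0.06 0.07 0.07 0.02 0.28 0.23 0.05 0.03 0.14 1.59
0.001 1.43 3.95 0.13 0.001 3.98 3.33 0.13 0.25 0.08 0.07
0.41 0.02 0.43 0.05 0.27 0.25 0.29 0.17 0.14 2.95 3.98 0.80
0.06 0.00005 0.12 0.02 1.50 0.06 0.07 0.09 0.17 1.00 2.16 0.03 0.63
0.52 0.42 0.27 0.06 0.001 0.95 0.11 0.01 0.73 0.07 0.29 0.43 0.07 0.08
3.26 0.25 2.51 0.49 4.04 0.45 0.57 2.47 0.20 0.18 0.45 3.04 0.75 0.62 1.51
4.04 0.09 1.77 0.07 0.34 0.15 0.24 0.03 0.24 2.14 0.27 0.71 3.35 0.09 1.11 3.91
0.03 1.21 0.10 0.19 2.09 0.01 0.18 0.25 0.02 0.07 0.42 0.32 0.21 0.52 0.06 0.34 0.02
0.02 0.22 1.44 0.41 3.73 0.75 0.27 0.09 4.15 0.17 0.21 0.39 0.30 3.90 0.22 0.52 0.13 0.78
2.31 0.06 0.09 0.13 1.69 0.01 0.32 0.54 0.001 9.41 0.84 0.05 2.49 0.66 0.08 0.38 1.51 0.14 0.16

0.04 0.01 0.06 0.02 0.01 0.02 0.02 0.04 0.01 0.11 0.16 0.03 0.09 0.09 0.03 0.10 0.06 0.02 0.05 0.05
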