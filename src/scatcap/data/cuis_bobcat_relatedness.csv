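bobcat_a,bobcat_b,r_ml,r_triadic,category
1,2,0.00,0.00,U
1,3,0.74,0.73,FS
1,4,0.54,0.16,FS
1,5,0.00,0.00,U
1,6,0.60,0.11,PO
1,7,0.00,0.13,U
1,8,0.00,0.00,U
1,9,0.00,0.00,U
2,3,0.00,0.00,U
2,4,0.00,0.01,U
2,5,0.50,0.24,PO
2,6,0.00,0.01,U
2,7,0.00,0.00,U
2,8,0.00,0.00,U
2,9,0.00,0.00,U
3,4,0.63,0.14,FS
3,5,0.00,0.00,U
3,6,0.72,0.29,FS
3,7,0.00,0.06,U
3,8,0.10,0.00,U
3,9,0.00,0.00,U
4,5,0.03,0.00,U
4,6,0.56,0.58,FS
4,7,0.00,0.00,U
4,8,0.41,0.02,PO
4,9,0.00,0.00,U
5,6,0.00,0.00,U
5,7,0.00,0.00,U
5,8,0.13,0.02,U
5,9,0.00,0.00,U
6,7,0.00,0.00,U
6,8,0.12,0.00,U
6,9,0.00,0.00,U
7,8,0.00,0.00,U
7,9,0.00,0.00,U
8,9,0.50,0.30,PO
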