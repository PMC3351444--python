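cycle,sequence,ec50_nM,ec50_sd,t_half_min,t_half_sd
0,YFPGNFAFS,9.96,4.42,16,2
0,YLPGQFfFS,0.77,0.37,24,3
0,YFPGQYAFF,1.89,0.90,26,8
0,YFPGQFAFG,0.79,0.54,13,1
0,YFPGHFAFS,6.63,2.91,17,4
1,FLPGQYAFS,2.75,0.14,28,1
1,YLPGQYAFL,5.75,2.56,27,4
1,YLPGQFAFs,1.72,0.32,31,0
1,YVPGQFAFf,4.17,2.31,42,19
1,yLPGQYAFF,9.23,3.68,135,39
2,fLPGQYAFf,8.20,3.96,1157,41
2,YLPGQYAFf,0.21,0.22,36,4
2,YLPGQYAFs,0.40,0.23,22,2
2,yLPGQYAFS,3.62,2.91,77,5
2,YRPGQYAFs,8.62,5.01,21,4
3,YLPaQYAFs,4.42,3.41,110,26
3,YLPGQYwFf,3.24,1.02,159,56
3,YLPqQYAFf,4.24,1.87,87,19
3,yLPsQYAFf,0.49,0.13,1693,291
3,yLPsQYAFs,2.90,1.34,1408,85
wt,YFPGQFAFS,1.29,1.54,24,6
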