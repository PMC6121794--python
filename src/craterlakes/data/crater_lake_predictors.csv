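lake,n_founder,t_col,admix,ne_longterm,mean_depth,littoral_area
Apoyeque,111,577,0.162,,,
Apoyo,263,1678,0.043,,,
As. Managua,32,797,0.323,,,
As. Leon,169,1550,0.119,,,
Masaya,8614,1561,0.210,,,
Xiloa,146,1318,0.286,,,
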