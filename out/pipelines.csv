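rank,population,total_mi,representative_source,representative_sink,n_residues
0,41,55.755149,A:6:,A:3:,43
1,5,0.078861,A:6:,A:54:,6
2,2,0.042837,A:6:,A:34:,6
3,1,0.992132,A:6:,A:55:,4
4,1,0.520006,A:6:,A:60:,5
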