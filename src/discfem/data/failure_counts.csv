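scenario,large_aff,small_aff,large_epjf,small_epjf,total_score
1,6,0,6,0,12
2,4,0,3,3,8.5
3,4,1,3,0,7.5
4,1,4,1,1,4.5
5,0,0,0,0,0
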