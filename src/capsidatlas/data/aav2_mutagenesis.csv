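residue,result,source
227,Disrupt,ref014
231,Disrupt,ref014
232,Disrupt,ref014
292,Disrupt,ref014
294,Disrupt,ref020
297,Disrupt,ref020
298,Disrupt,ref020
334,Non-Disrupt,ref016
337,Non-Disrupt,ref016
382,Non-Disrupt,ref018
389,Non-Disrupt,ref020
397,Disrupt,ref020
402,Disrupt,ref020
661,Non-Disrupt,ref020
692,Disrupt,ref020
694,Disrupt,ref020
696,Disrupt,ref014
704,Non-Disrupt,ref018
706,Non-Disrupt,ref018
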