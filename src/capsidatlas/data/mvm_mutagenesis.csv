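residue,result,source
55,Disrupt,ref017
129,Disrupt,ref017
153,Disrupt,ref017
168,Non-Disrupt,ref017
261,Non-Disrupt,ref020
302,Disrupt,ref019
507,Non-Disrupt,ref020
540,Non-Disrupt,ref020
543,Disrupt,ref017
546,Disrupt,ref017
567,Disrupt,ref019
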