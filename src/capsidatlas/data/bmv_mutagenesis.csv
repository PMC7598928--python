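residue,result,source
51,Disrupt,ref015
180,Partial Disrupt,ref015
181,Disrupt,ref015
182,Disrupt,ref015
183,Partial Disrupt,ref015
184,Disrupt,ref015
185,Non-Disrupt,ref015
188,Partial Disrupt,ref015
189,Partial Disrupt,ref015
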