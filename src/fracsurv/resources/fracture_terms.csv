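term,match_mode,concept_id
fraktur,substring,RID4650
fissur,substring,RID4650
bruch,substring,RID4650
infraktion,token,RID4650
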