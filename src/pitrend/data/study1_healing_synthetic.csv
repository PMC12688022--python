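round,vignette,score
1,V1,2
1,V2,3
1,V3,3
2,V1,2
2,V2,3
2,V3,3
2,V4,4
3,V1,3
3,V2,3
3,V3,3
3,V4,4
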