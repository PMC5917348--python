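patient_id,stage,n_regions,r1_lpv,r2_rpv,r3_pla,r4_sra,r5_ira,r6_ala,r7_iag
3,ecgi,4,1,1,1,0,0,0,1
3,pre,3,0,0,1,1,0,0,1
3,post1,2,0,0,0,1,1,0,0
3,post2,3,1,0,0,1,1,0,0
4,ecgi,3,1,1,0,1,0,0,0
4,pre,3,0,0,0,1,1,0,1
4,post1,5,1,0,1,1,1,0,1
4,post2,4,1,0,1,1,1,0,0
5,ecgi,2,1,1,0,0,0,0,0
5,pre,3,1,1,1,0,0,0,0
5,post1,3,0,1,0,0,0,1,1
5,post2,2,0,1,0,0,0,1,0
8,ecgi,4,1,1,1,1,0,0,0
8,pre,3,1,0,0,1,0,1,0
8,post1,1,0,0,0,0,1,0,0
8,post2,2,0,0,0,0,1,1,0
9,ecgi,5,1,1,1,0,0,1,1
9,pre,4,0,1,1,1,1,0,0
9,post1,3,0,1,0,1,1,0,0
9,post2,3,1,1,0,0,1,0,0
11,ecgi,2,1,1,0,0,0,0,0
11,pre,2,1,0,1,0,0,0,0
11,post1,2,1,0,1,0,0,0,0
11,post2,1,1,0,0,0,0,0,0
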