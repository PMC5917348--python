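{
 "classwise_regional.csv": "e47225d6d4100a69db5f7365ae3d14439de39d6d82ed1419d027bd59c49cbdba",
 "concordance.csv": "7e44e42e10e0fb0ff9f7ca15c473bb5b377520e388f2937483397dc2e4f6c153",
 "outcome_counts.csv": "0909b94af29fb755e2b3c203763fb5b971b9076ba8305caf7c93917a35dd8ce9",
 "regional_counts.csv": "5d2a7a70f662bfd3f57534b2c50838d209b47ee94d9a0dda45c2139d40582e35",
 "table1.csv": "67fae2dda6e07150266f06bb96cf239114b7db8e784fdf6538a0eeb4003a3440",
 "table2.csv": "0d803ebe9a6c156bdbf7579f03caab776d68270e86434a7d4d47b5f5d74ed0bc"
}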