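method,151507,151508,151509,151510,151673,151674,151675,151676,BC1,STARmap
ADEPT,0.669,0.614,0.614,0.639,0.713,0.697,0.683,0.613,0.610,0.677
STAGATE,0.592,0.646,0.596,0.571,0.637,0.609,0.607,0.552,0.536,0.406
CCST,0.558,0.527,0.558,0.529,0.548,0.505,0.617,0.578,0.585,0.318
SEDR,0.527,0.476,0.521,0.505,0.590,0.542,0.554,0.552,0.545,0.353
SpaGCN,0.551,0.503,0.573,0.570,0.556,0.502,0.502,0.461,0.606,0.496
BayesSpace,0.491,0.453,0.468,0.438,0.552,0.440,0.455,0.441,0.528,0.379
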