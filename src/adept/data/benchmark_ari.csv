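method,151507,151508,151509,151510,151673,151674,151675,151676,BC1,STARmap
ADEPT,0.543,0.492,0.537,0.534,0.603,0.510,0.649,0.586,0.563,0.611
STAGATE,0.572,0.479,0.473,0.489,0.537,0.486,0.589,0.562,0.481,0.496
CCST,0.444,0.400,0.434,0.390,0.455,0.385,0.492,0.505,0.549,0.147
SEDR,0.434,0.352,0.376,0.356,0.485,0.452,0.451,0.474,0.507,0.230
SpaGCN,0.461,0.382,0.455,0.446,0.465,0.403,0.400,0.340,0.572,0.379
BayesSpace,0.380,0.338,0.323,0.291,0.460,0.320,0.352,0.335,0.489,0.262
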