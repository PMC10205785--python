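method,151507,151508,151509,151510,151673,151674,151675,151676,BC1,STARmap
ADEPT,0.836,0.709,0.755,0.755,0.821,0.755,0.774,0.726,0.655,0.824
STAGATE,0.691,0.737,0.717,0.690,0.743,0.670,0.709,0.636,0.580,0.555
CCST,0.756,0.693,0.630,0.640,0.718,0.617,0.747,0.718,0.668,0.578
SEDR,0.666,0.577,0.619,0.617,0.715,0.665,0.686,0.693,0.596,0.552
SpaGCN,0.694,0.620,0.681,0.667,0.674,0.574,0.617,0.556,0.657,0.461
BayesSpace,0.620,0.532,0.578,0.545,0.666,0.536,0.582,0.555,0.537,0.441
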