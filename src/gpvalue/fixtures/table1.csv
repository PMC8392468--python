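state,observed_mean,uk_mean,uk_sd,crude_mean,crude_sd,model1_mean,model1_sd
111111,1,1,0,1,0,1,0
111621,0.8244,0.7482,0.0345,0.8276,0.0264,0.8218,0.0269
113411,0.8544,0.7284,0.031,0.8713,0.0207,0.8637,0.022
115653,0.7306,0.5652,0.0561,0.7073,0.0272,0.7116,0.0277
121212,0.8422,0.8275,0.0261,0.8867,0.0194,0.8741,0.0209
122233,0.8694,0.7475,0.034,0.8512,0.0235,0.8562,0.0259
122425,0.7582,0.6784,0.0353,0.7686,0.0234,0.7652,0.0241
124125,0.8478,0.7292,0.0475,0.8269,0.0245,0.835,0.0258
131542,0.8283,0.6181,0.0304,0.8038,0.0236,0.7953,0.0257
132524,0.7633,0.6574,0.037,0.7692,0.022,0.775,0.0232
133132,0.8583,0.6942,0.0343,0.8517,0.0227,0.8467,0.0244
135312,0.7556,0.6992,0.0488,0.7795,0.0221,0.7757,0.0229
142154,0.7912,0.6844,0.0373,0.7527,0.0287,0.7569,0.0294
144341,0.7418,0.72,0.0279,0.7335,0.0249,0.7425,0.0255
211111,0.89,0.9197,0.0215,0.9434,0.0169,0.9176,0.0248
212145,0.785,0.6927,0.0446,0.7693,0.0266,0.7591,0.0278
213323,0.7833,0.7761,0.0296,0.8048,0.0208,0.8093,0.0215
221452,0.8239,0.6237,0.0459,0.8178,0.0234,0.8148,0.0254
224612,0.6461,0.6256,0.0392,0.7043,0.0238,0.6897,0.0244
232111,0.8576,0.6987,0.0377,0.8525,0.0251,0.8336,0.0273
235224,0.7676,0.6486,0.0335,0.7505,0.0241,0.7541,0.025
241531,0.785,0.702,0.0352,0.7592,0.0251,0.7646,0.0266
312332,0.8639,0.7472,0.0285,0.8207,0.0227,0.8348,0.0252
315515,0.6983,0.6642,0.0363,0.7058,0.0247,0.7152,0.0247
321122,0.8583,0.7638,0.0266,0.8527,0.0218,0.8542,0.0234
323644,0.5717,0.5362,0.0287,0.6335,0.0256,0.6201,0.0257
332411,0.8435,0.7217,0.0376,0.8125,0.0247,0.8289,0.0265
334251,0.7347,0.6761,0.0532,0.7229,0.0251,0.7344,0.0258
341123,0.8311,0.7009,0.0393,0.8055,0.0248,0.8085,0.0259
412152,0.7933,0.6558,0.0371,0.7466,0.0251,0.7454,0.0277
414522,0.7556,0.6612,0.0301,0.7505,0.023,0.7597,0.0235
421314,0.8117,0.6689,0.0368,0.8067,0.0236,0.8066,0.025
425131,0.6578,0.6771,0.0551,0.6973,0.0236,0.6935,0.0247
431443,0.8247,0.638,0.0339,0.7775,0.027,0.7935,0.0274
432621,0.7429,0.6468,0.0487,0.734,0.0237,0.7428,0.0254
443215,0.7306,0.6548,0.0352,0.6718,0.0274,0.6746,0.0283
511114,0.8578,0.6993,0.0379,0.8406,0.0247,0.8387,0.0267
512242,0.6028,0.6906,0.0324,0.6647,0.0244,0.6573,0.0244
522321,0.7778,0.6846,0.0324,0.7658,0.023,0.7654,0.0253
523551,0.6072,0.6201,0.0471,0.6399,0.0257,0.6404,0.0261
531635,0.7865,0.5323,0.0345,0.7258,0.0302,0.7438,0.0302
534113,0.7235,0.7106,0.0437,0.7078,0.0249,0.7173,0.026
545422,0.7006,0.6351,0.0322,0.6181,0.029,0.6365,0.0292
611221,0.8211,0.6667,0.0521,0.7922,0.0253,0.7918,0.0275
614434,0.5611,0.6497,0.0383,0.5826,0.0273,0.5922,0.0273
622513,0.7072,0.5809,0.0392,0.6949,0.0259,0.6894,0.0275
625141,0.5106,0.5561,0.0466,0.5755,0.0273,0.5582,0.028
631355,0.7406,0.5823,0.0354,0.6749,0.0311,0.6948,0.0306
633122,0.7141,0.6515,0.0338,0.6912,0.0249,0.6943,0.0261
642612,0.685,0.5594,0.0336,0.6228,0.029,0.6633,0.0299
645655,0.3222,0.3575,0.0186,0.3463,0.0252,0.3292,0.0237
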