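model,q2,N,SEP,SEE,r2_ncv,F,S,E,H,D,A
S,0.293,3,1.042,0.903,0.470,20.383,1,,,,
E,0.534,10,0.893,0.476,0.867,40.592,,1,,,
H,0.317,4,1.032,0.788,0.602,25.722,,,1,,
D,0.253,8,1.112,1.031,0.359,4.482,,,,1,
A,0.520,5,0.871,0.638,0.743,38.785,,,,,1
SE,0.519,10,0.907,0.417,0.898,54.799,0.314,0.686,,,
SEH,0.534,8,0.879,0.216,0.977,110.701,0.183,0.492,0.324,,
SEHD,0.628,7,0.779,0.382,0.910,94.448,0.159,0.458,0.260,0.123,
SEHA,0.688,7,0.713,0.332,0.933,128.486,0.131,0.346,0.177,,0.347
SED,0.626,9,0.793,0.382,0.913,73.600,0.245,0.639,,0.116,
SEA,0.725,7,0.670,0.350,0.925,114.665,0.182,0.387,,,0.421
SEDA,0.765,7,0.620,0.327,0.934,132.475,0.154,0.357,,0.099,0.389
SH,0.316,4,1.033,0.772,0.618,27.502,0.408,,0.592,,
SD,0.364,19,1.128,0.525,0.862,17.433,0.814,,,0.186,
SA,0.572,7,0.836,0.484,0.857,55.453,0.344,,,,0.656
SHD,0.426,3,0.939,0.799,0.585,32.396,0.219,,0.479,0.303,
SHA,0.529,6,0.870,0.483,0.855,64.909,0.201,,0.303,,0.496
SDA,0.719,7,0.678,0.404,0.900,83.485,0.235,,,0.210,0.555
SHDA,0.673,7,0.731,0.366,0.918,103.744,0.156,,0.240,0.164,0.440
EH,0.550,10,0.877,0.391,0.911,63.307,,0.537,0.427,,
ED,0.616,9,0.804,0.407,0.902,64.163,,0.856,,0.144,
EA,0.701,6,0.693,0.408,0.896,95.020,,0.498,,,0.502
EHD,0.641,8,0.771,0.376,0.915,85.695,,0.525,0.343,0.132,
EHA,0.691,7,0.710,0.390,0.925,115.138,,0.390,0.234,,0.376
EDA,0.752,7,0.636,0.366,0.918,103.539,,0.453,,0.111,0.437
EHDA,0.742,8,0.654,0.311,0.942,128.936,,0.341,0.211,0.093,0.355
HD,0.428,9,0.981,0.528,0.834,35.186,,,0.804,0.196,
HA,0.537,6,0.862,0.493,0.849,61.685,,,0.426,,0.574
HDA,0.682,10,0.738,0.331,0.936,90.828,,,0.356,0.155,0.490
DA,0.705,11,0.716,0.465,0.876,39.132,,,,0.240,0.760
SEHDA,0.734,7,0.659,0.320,0.937,138.360,0.110,0.304,0.156,0.100,0.330
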