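property,A,C,D,E,F,G,H,I,K,L,M,N,P,Q,R,S,T,V,W,Y
p01,83.393,82.555,82.188,80.863,82.559,82.314,84.412,82.358,81.241,83.484,81.447,83.094,78.906,83.757,81.792,80.864,80.675,83.966,81.015,83.879
p02,100.232,102.169,99.527,112.321,102.343,111.554,105.761,108.647,95.587,111.935,92.032,103.997,103.296,114.168,104.440,117.432,109.873,96.585,107.208,96.048
p03,78.008,56.145,39.854,75.335,85.680,41.590,65.347,54.394,88.159,58.170,94.349,28.337,72.692,82.889,38.248,57.220,51.759,45.396,26.503,54.350
p04,17.117,17.847,14.462,15.444,17.819,14.777,16.371,15.477,14.747,14.380,16.278,14.885,17.399,17.353,15.201,14.186,12.940,16.575,15.030,16.160
p05,83.658,77.455,64.500,86.189,79.141,47.192,53.976,73.673,66.736,49.526,48.690,66.525,76.231,57.595,70.869,73.780,46.389,65.445,48.940,56.216
p06,89.832,89.928,91.318,90.779,90.979,91.356,91.394,91.499,91.042,91.189,91.189,90.529,89.741,90.737,91.294,91.151,90.995,90.350,90.955,90.215
p07,87.943,77.458,85.986,87.373,93.290,71.597,87.201,93.587,75.104,90.453,82.934,82.466,95.722,88.236,91.175,71.937,91.828,92.756,91.630,99.931
p08,99.127,99.040,98.474,98.727,99.602,99.853,99.002,97.985,98.825,99.158,98.676,97.923,98.724,99.542,98.595,99.204,98.376,99.330,97.192,98.613
p09,8.714,9.088,7.832,8.772,9.084,8.184,11.358,10.116,10.430,9.591,9.170,5.503,6.313,10.028,7.317,8.463,8.135,8.404,10.208,8.682
p10,116.848,125.765,123.288,108.579,117.377,110.184,120.343,112.559,109.903,127.541,126.147,116.088,115.850,119.711,127.762,108.600,116.405,118.448,121.305,123.269
p11,55.787,44.783,36.635,24.578,56.096,72.869,58.792,33.149,41.300,41.915,54.008,40.439,58.061,51.168,58.532,50.943,47.811,45.051,22.594,59.739
p12,16.271,20.138,18.684,26.281,19.980,25.276,15.041,23.684,10.963,14.938,7.442,15.341,13.962,25.754,15.333,19.886,16.519,15.849,11.427,0.242
p13,9.372,8.330,7.755,7.726,9.098,8.566,8.084,8.246,7.437,8.320,8.700,8.003,8.300,8.378,8.720,7.687,9.941,9.550,8.969,9.175
p14,27.470,27.807,27.670,28.272,28.515,28.607,27.232,27.810,27.449,27.174,28.195,27.724,27.693,27.611,27.641,27.062,27.853,27.021,27.796,28.064
p15,83.504,62.854,89.909,72.416,91.362,73.985,71.262,55.471,52.230,74.529,92.467,69.602,59.873,74.609,87.962,77.238,80.878,82.424,76.195,75.723
p16,82.543,71.115,99.611,113.271,101.373,101.445,84.190,86.317,112.699,117.247,107.994,109.010,104.112,108.346,116.007,101.036,95.556,98.402,113.607,115.624
p17,60.330,59.848,60.376,60.176,59.871,60.345,60.949,60.030,60.511,60.767,59.517,61.733,60.195,60.892,59.348,60.187,61.299,60.659,60.741,60.474
p18,33.812,33.699,33.303,34.033,33.617,32.613,33.659,33.999,33.698,33.725,34.846,33.377,33.753,33.435,33.574,33.969,34.056,33.401,33.331,33.600
p19,53.150,53.724,56.261,56.613,53.925,50.999,54.533,54.863,53.569,57.264,53.105,54.933,56.989,56.031,55.192,53.827,55.081,55.237,53.866,56.491
p20,107.896,103.352,121.541,69.584,73.667,68.482,57.783,77.017,107.187,86.179,61.874,113.615,68.000,78.823,78.061,123.608,65.985,79.697,85.354,102.421
p21,13.816,25.368,23.186,14.902,16.547,24.285,31.159,12.972,17.130,35.930,19.855,9.059,31.512,27.108,24.753,27.621,19.012,26.304,23.707,17.375
p22,108.559,121.765,118.835,130.350,128.193,109.695,117.792,111.939,126.219,120.352,120.294,119.022,128.100,114.459,118.275,115.526,124.424,116.286,116.200,125.480
p23,87.669,88.009,88.594,88.912,88.499,89.676,87.966,88.473,88.281,87.304,88.050,88.598,87.240,87.903,87.503,88.626,89.035,89.170,86.904,88.534
p24,79.307,78.730,77.855,78.905,79.023,78.904,78.192,79.563,80.658,80.253,78.220,77.498,78.990,80.044,78.926,80.381,78.556,79.005,77.215,79.107
p25,96.497,96.779,96.721,96.222,96.509,96.369,96.738,96.780,96.626,96.078,97.140,96.574,96.397,96.572,97.614,96.036,96.478,96.495,96.569,96.126
p26,22.336,22.242,22.107,22.458,22.416,22.331,22.344,22.220,22.447,22.256,22.573,22.336,22.336,22.287,22.526,22.183,22.469,22.023,22.410,22.504
p27,23.149,22.423,22.424,23.166,22.567,21.846,23.302,23.194,21.863,22.661,22.342,22.894,22.266,22.273,22.186,22.953,22.045,22.661,22.647,21.808
p28,0.516,0.570,0.773,0.708,0.525,0.389,0.633,0.606,0.755,0.754,0.830,0.685,0.697,0.596,0.531,0.678,0.704,1.017,0.622,0.616
p29,117.846,117.791,117.565,117.497,117.736,118.216,117.641,117.936,117.891,117.905,117.681,117.833,117.982,117.764,117.669,117.801,117.714,117.782,117.514,118.092
p30,29.943,28.314,3.221,29.044,12.261,-10.682,25.059,14.588,24.560,21.254,18.584,22.516,14.447,17.767,28.262,40.618,36.396,22.342,8.791,11.729
p31,56.804,56.603,56.713,56.543,56.787,56.678,56.642,56.881,56.854,56.513,56.831,56.697,56.921,56.968,56.910,56.797,56.458,56.785,56.452,56.696
p32,43.782,43.181,43.387,43.337,43.475,43.582,43.715,43.134,43.616,43.744,44.012,43.985,44.123,43.543,43.799,44.167,43.507,43.599,43.689,43.221
p33,26.899,26.685,23.947,21.505,29.011,23.420,22.686,27.406,25.222,29.702,19.204,22.326,25.743,19.898,17.711,27.983,29.798,17.658,22.817,17.611
p34,112.594,110.992,110.057,126.045,112.338,110.672,97.076,115.475,116.696,96.907,92.627,98.378,103.168,106.334,105.015,114.921,106.746,103.580,112.722,114.150
p35,50.242,54.078,57.030,63.719,51.453,53.535,53.688,49.852,54.728,42.117,59.226,51.860,47.040,54.906,60.519,51.124,47.801,54.608,61.647,43.318
p36,32.640,36.083,33.360,39.072,36.375,34.660,37.015,36.541,34.910,33.936,33.077,36.365,35.770,37.373,37.016,35.570,34.399,32.406,31.900,34.064
p37,63.827,93.204,93.600,95.620,70.001,85.348,92.015,60.672,57.894,115.845,112.134,106.036,111.511,101.568,107.412,78.581,87.966,100.463,112.662,97.555
p38,75.495,83.544,84.121,78.125,83.856,75.032,71.512,65.413,85.573,74.917,81.864,81.317,92.960,73.006,67.868,75.723,77.749,71.612,87.203,74.359
p39,116.644,115.838,118.920,116.056,117.964,116.745,117.540,118.821,116.798,116.210,117.318,115.772,118.269,118.378,115.701,117.040,116.199,117.807,117.830,119.102
p40,4.253,19.237,9.117,-3.198,-3.060,-18.531,8.844,-18.869,1.094,7.840,-14.073,6.721,-22.977,7.406,31.477,3.948,-12.502,-2.684,-4.076,16.021
p41,-4.970,5.005,14.797,6.394,17.618,9.021,23.083,16.453,4.650,7.821,16.407,4.874,-0.476,2.668,16.042,19.197,15.890,3.448,4.406,11.583
p42,113.883,109.008,107.363,105.303,110.220,112.172,109.713,108.339,109.911,109.755,110.873,110.559,106.600,107.328,110.473,110.008,107.895,109.802,109.344,107.755
p43,18.667,18.219,17.706,18.374,18.451,18.746,17.988,18.776,19.504,19.095,18.513,18.219,18.106,18.533,18.706,18.932,17.980,17.685,19.344,18.829
p44,42.340,42.594,42.627,42.624,42.769,42.253,42.092,42.607,42.572,42.174,41.998,42.700,42.710,41.933,42.445,42.651,42.498,42.828,42.331,42.760
p45,52.049,52.247,52.002,51.512,52.030,52.323,52.090,51.266,51.987,51.434,52.048,51.278,51.587,51.644,51.491,51.469,51.714,51.587,51.519,51.833
p46,94.217,94.308,94.302,94.311,94.433,94.470,94.164,94.319,94.411,94.320,94.351,94.503,94.233,94.387,94.394,94.332,94.377,94.299,94.472,94.471
p47,57.627,58.146,58.351,58.226,57.778,57.509,58.025,58.139,58.166,57.924,58.051,58.005,58.819,57.844,58.619,57.589,57.827,58.589,58.288,58.502
p48,94.992,103.510,116.280,108.993,90.304,111.202,115.295,127.391,110.235,104.007,101.617,102.849,97.416,134.546,109.285,98.690,124.043,120.097,113.106,102.444
p49,20.014,20.241,20.300,20.443,20.029,20.044,20.317,20.077,20.319,20.330,20.075,20.521,20.114,20.128,20.143,20.388,20.520,20.445,20.430,20.630
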