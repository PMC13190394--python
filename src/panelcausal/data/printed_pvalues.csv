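country,direction,statistic,p_value
Austria,co2->migr,1.049,0.306
Belgium,co2->migr,1.362,0.506
France,co2->migr,5.623,0.060
Germany,co2->migr,0.135,0.935
Italy,co2->migr,15.020,0.002
Luxembourg,co2->migr,0.129,0.720
Czechia,co2->migr,0.320,0.572
Estonia,co2->migr,5.219,0.022
Finland,co2->migr,0.001,0.972
Hungary,co2->migr,0.523,0.470
Lithuania,co2->migr,8.832,0.032
Malta,co2->migr,0.945,0.815
Portugal,co2->migr,0.191,0.662
Slovak Republic,co2->migr,8.981,0.030
Sweden,co2->migr,10.991,0.012
Slovenia,co2->migr,3.758,0.289
Spain,co2->migr,3.373,0.338
Latvia,co2->migr,8.525,0.036
Ireland,co2->migr,5.214,0.157
Greece,co2->migr,7.295,0.063
Denmark,co2->migr,0.411,0.814
Croatia,co2->migr,0.723,0.868
Bulgaria,co2->migr,1.603,0.449
Netherlands,co2->migr,3.916,0.141
Cyprus,co2->migr,4.045,0.132
Poland,co2->migr,0.510,0.917
Romania,co2->migr,19.058,0.000
Austria,migr->co2,0.006,0.941
Belgium,migr->co2,2.259,0.323
France,migr->co2,0.234,0.890
Germany,migr->co2,3.545,0.170
Italy,migr->co2,10.035,0.018
Luxembourg,migr->co2,0.952,0.329
Czechia,migr->co2,0.012,0.912
Estonia,migr->co2,0.157,0.692
Finland,migr->co2,1.928,0.165
Hungary,migr->co2,3.512,0.061
Lithuania,migr->co2,3.877,0.275
Malta,migr->co2,16.399,0.001
Portugal,migr->co2,1.978,0.160
Slovak Republic,migr->co2,2.882,0.410
Sweden,migr->co2,1.790,0.617
Slovenia,migr->co2,4.095,0.251
Spain,migr->co2,5.210,0.157
Latvia,migr->co2,1.297,0.730
Ireland,migr->co2,4.480,0.214
Greece,migr->co2,2.984,0.394
Denmark,migr->co2,10.533,0.005
Croatia,migr->co2,20.105,0.000
Bulgaria,migr->co2,2.730,0.255
Netherlands,migr->co2,0.577,0.749
Cyprus,migr->co2,5.054,0.080
Poland,migr->co2,4.831,0.185
Romania,migr->co2,2.781,0.249
Austria,hexp->migr,5.382,0.146
Belgium,hexp->migr,5.358,0.069
France,hexp->migr,13.041,0.005
Germany,hexp->migr,4.914,0.178
Italy,hexp->migr,2.318,0.509
Luxembourg,hexp->migr,1.870,0.600
Czechia,hexp->migr,4.178,0.124
Estonia,hexp->migr,3.644,0.056
Finland,hexp->migr,5.356,0.069
Hungary,hexp->migr,9.284,0.026
Lithuania,hexp->migr,0.521,0.914
Malta,hexp->migr,7.295,0.063
Portugal,hexp->migr,6.615,0.085
Slovak Republic,hexp->migr,7.842,0.049
Sweden,hexp->migr,4.147,0.246
Slovenia,hexp->migr,7.578,0.056
Spain,hexp->migr,0.201,0.654
Latvia,hexp->migr,0.321,0.571
Ireland,hexp->migr,0.126,0.939
Greece,hexp->migr,0.314,0.855
Denmark,hexp->migr,2.652,0.266
Croatia,hexp->migr,5.733,0.125
Bulgaria,hexp->migr,0.490,0.783
Netherlands,hexp->migr,2.105,0.349
Cyprus,hexp->migr,0.054,0.817
Poland,hexp->migr,2.353,0.125
Romania,hexp->migr,0.089,0.766
Austria,migr->hexp,8.184,0.042
Belgium,migr->hexp,0.175,0.916
France,migr->hexp,0.589,0.899
Germany,migr->hexp,3.356,0.340
Italy,migr->hexp,6.618,0.085
Luxembourg,migr->hexp,3.721,0.293
Czechia,migr->hexp,0.529,0.768
Estonia,migr->hexp,0.017,0.896
Finland,migr->hexp,0.089,0.956
Hungary,migr->hexp,5.698,0.127
Lithuania,migr->hexp,0.054,0.997
Malta,migr->hexp,3.175,0.365
Portugal,migr->hexp,7.824,0.050
Slovak Republic,migr->hexp,0.958,0.811
Sweden,migr->hexp,20.038,0.000
Slovenia,migr->hexp,12.951,0.005
Spain,migr->hexp,4.872,0.027
Latvia,migr->hexp,0.694,0.405
Ireland,migr->hexp,3.727,0.155
Greece,migr->hexp,1.999,0.368
Denmark,migr->hexp,1.658,0.437
Croatia,migr->hexp,0.627,0.890
Bulgaria,migr->hexp,12.458,0.002
Netherlands,migr->hexp,1.154,0.562
Cyprus,migr->hexp,2.768,0.096
Poland,migr->hexp,0.000,0.990
Romania,migr->hexp,0.022,0.882
Austria,hexp->co2,4.330,0.228
Belgium,hexp->co2,2.393,0.495
France,hexp->co2,1.906,0.386
Germany,hexp->co2,5.996,0.050
Italy,hexp->co2,1.547,0.214
Luxembourg,hexp->co2,0.056,0.813
Czechia,hexp->co2,3.517,0.061
Estonia,hexp->co2,16.396,0.000
Finland,hexp->co2,4.909,0.027
Hungary,hexp->co2,3.804,0.283
Lithuania,hexp->co2,0.375,0.541
Malta,hexp->co2,24.973,0.000
Portugal,hexp->co2,0.003,0.958
Slovak Republic,hexp->co2,0.448,0.503
Sweden,hexp->co2,5.311,0.070
Slovenia,hexp->co2,2.808,0.094
Spain,hexp->co2,0.250,0.617
Latvia,hexp->co2,0.495,0.482
Ireland,hexp->co2,1.443,0.230
Greece,hexp->co2,1.775,0.183
Denmark,hexp->co2,3.754,0.289
Croatia,hexp->co2,8.376,0.039
Bulgaria,hexp->co2,0.025,0.874
Netherlands,hexp->co2,2.406,0.121
Cyprus,hexp->co2,0.106,0.745
Poland,hexp->co2,5.730,0.057
Romania,hexp->co2,6.063,0.109
Austria,co2->hexp,7.179,0.066
Belgium,co2->hexp,3.064,0.382
France,co2->hexp,7.057,0.029
Germany,co2->hexp,9.144,0.010
Italy,co2->hexp,1.878,0.171
Luxembourg,co2->hexp,0.296,0.587
Czechia,co2->hexp,1.664,0.197
Estonia,co2->hexp,4.346,0.114
Finland,co2->hexp,2.106,0.147
Hungary,co2->hexp,12.356,0.006
Lithuania,co2->hexp,9.666,0.002
Malta,co2->hexp,3.257,0.354
Portugal,co2->hexp,0.015,0.903
Slovak Republic,co2->hexp,1.570,0.210
Sweden,co2->hexp,8.060,0.018
Slovenia,co2->hexp,1.075,0.300
Spain,co2->hexp,0.449,0.503
Latvia,co2->hexp,2.017,0.156
Ireland,co2->hexp,0.163,0.686
Greece,co2->hexp,0.494,0.482
Denmark,co2->hexp,0.776,0.855
Croatia,co2->hexp,19.483,0.000
Bulgaria,co2->hexp,0.015,0.901
Netherlands,co2->hexp,1.041,0.308
Cyprus,co2->hexp,0.231,0.631
Poland,co2->hexp,8.332,0.016
Romania,co2->hexp,4.632,0.201
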