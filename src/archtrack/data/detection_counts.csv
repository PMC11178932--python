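date,session,instances,tp,fp,fn,recall_printed,precision_printed,accuracy_printed
2023-01-03,M,9247,8855,392,0,100.0,95.76,95.76
2023-01-03,E,8075,8000,75,0,100.0,99.07,99.07
2023-01-05,M,13631,13552,56,23,99.83,99.59,99.59
2023-01-05,E,8563,8511,35,17,99.8,99.59,99.59
2023-01-06,M,5059,4982,77,0,100.0,98.48,98.48
2023-01-07,M,5106,5106,0,0,100.0,100.0,100.0
2023-01-10,M,10418,10097,321,0,100.0,96.92,96.92
2023-01-10,E,10302,10228,74,0,100.0,99.28,99.28
2023-01-11,M,4476,4408,68,0,100.0,98.48,98.48
2023-01-11,E,6781,6770,11,0,100.0,99.84,99.84
2023-01-12,M,5422,5405,17,0,100.0,99.69,99.69
2023-01-12,E,10852,10814,38,0,100.0,99.65,99.65
2023-01-13,M,9170,9001,169,0,100.0,98.16,98.16
2023-01-13,E,15368,14797,571,0,100.0,96.28,96.28
2023-01-14,M,6074,6012,62,0,100.0,98.98,98.98
2023-01-23,M,6668,6611,57,0,100.0,99.15,99.15
2023-01-23,E,11911,11867,44,0,100.0,99.63,99.63
2023-01-24,M,12546,12450,96,0,100.0,99.23,99.23
2023-01-24,E,11138,10996,142,0,100.0,98.73,98.73
2023-01-25,M,7624,7587,37,0,100.0,99.51,99.51
2023-01-25,E,7972,7940,32,0,100.0,99.6,99.6
2023-01-26,M,6031,5963,68,0,100.0,98.87,98.87
2023-01-26,E,8967,8942,25,0,100.0,99.72,99.72
2023-01-27,M,11064,11032,32,0,100.0,99.71,99.71
2023-01-27,E,1870,1864,6,0,100.0,99.68,99.68
2023-01-28,M,15619,15422,197,0,100.0,98.74,98.74
2023-01-29,M,8168,8168,0,0,100.0,100.0,100.0
2023-01-29,E,9128,9065,63,0,100.0,99.31,99.31
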