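date,session,cattle,correct,wrong,accuracy_printed
2023-01-03,M,62,62,0,100.0
2023-01-03,E,56,56,0,100.0
2023-01-05,M,64,63,1,98.44
2023-01-05,E,65,64,1,98.46
2023-01-06,M,64,64,0,100.0
2023-01-07,M,42,41,1,97.62
2023-01-10,M,56,55,1,98.21
2023-01-10,E,56,56,0,100.0
2023-01-11,M,56,56,0,100.0
2023-01-11,E,63,63,0,100.0
2023-01-12,M,56,56,0,100.0
2023-01-12,E,58,57,1,98.28
2023-01-13,M,66,65,1,98.48
2023-01-13,E,54,54,0,100.0
2023-01-14,M,64,64,0,100.0
2023-01-23,M,63,63,0,100.0
2023-01-23,E,64,64,0,100.0
2023-01-24,M,55,54,1,98.18
2023-01-24,E,56,56,0,100.0
2023-01-25,M,58,58,0,100.0
2023-01-25,E,58,58,0,100.0
2023-01-26,M,52,52,0,100.0
2023-01-26,E,62,62,0,100.0
2023-01-27,M,27,27,0,100.0
2023-01-27,E,62,62,0,100.0
2023-01-28,M,41,41,0,100.0
2023-01-29,M,62,61,1,98.38
2023-01-29,E,62,62,0,100.0
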