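date,session,svm,rf,dt,adaboost,sgd
2023-01-03,M,75.81,67.74,70.97,80.65,45.16
2023-01-03,E,78.57,76.79,78.57,82.14,51.79
2023-01-05,M,71.88,71.88,60.94,73.44,42.19
2023-01-05,E,78.46,81.54,83.08,81.54,41.54
2023-01-06,M,78.12,68.75,76.56,73.44,40.62
2023-01-07,M,71.43,69.05,59.52,69.05,42.86
2023-01-10,M,83.93,78.57,85.71,80.36,50.0
2023-01-10,E,80.36,71.43,75.0,78.57,51.79
2023-01-11,M,69.64,67.86,76.79,75.0,44.64
2023-01-11,E,71.43,73.21,71.43,76.79,51.79
2023-01-12,M,71.43,79.37,79.37,79.37,46.03
2023-01-12,E,80.36,80.36,78.57,80.36,51.79
2023-01-23,M,71.43,76.19,80.95,80.95,50.79
2023-01-23,E,75.0,78.12,76.56,75.0,50.0
2023-01-24,M,71.7,73.58,77.36,77.36,56.6
2023-01-24,E,67.86,73.21,67.86,73.21,58.93
2023-01-25,M,73.21,71.43,76.79,78.57,35.71
2023-01-25,E,81.36,81.36,76.27,79.66,47.46
2023-01-26,E,76.92,82.69,78.85,84.62,51.92
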