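patient_id,fibre,n_deletions,nd4_nd1_load_pct,size1_kb,prop1,size2_kb,prop2,size3_kb,prop3,printed_largest_most_prevalent
P7,1,2,72,4,0.23,5,0.77,,,Yes
P7,2,1,32,5,1,,,,,
P7,3,2,73,6,0.69,7,0.31,,,No
P7,4,2,85,5,0.86,7,0.14,,,No
P7,5,1,69,7,1,,,,,
P7,6,1,29,5,1,,,,,
P7,7,2,84,4,0.28,5,0.72,,,Yes
P7,8,2,98,5,0.25,7,0.75,,,Yes
P7,9,1,83,7,1,,,,,
P7,10,1,u.m,5,1,,,,,
P7,11,1,28,5,1,,,,,
P7,12,1,83,7,1,,,,,
P7,13,2,82,6,0.42,7,0.58,,,Yes
P7,14,1,90,5,1,,,,,
P7,15,1,30,6,1,,,,,
P7,16,1,43,7,1,,,,,
P7,17,1,81,8,1,,,,,
P7,18,1,u.m,6,1,,,,,
P7,19,2,47,5,0.67,10,0.33,,,No
P7,20,1,86,6,1,,,,,
P7,21,1,81,5,1,,,,,
P7,22,1,95,5,1,,,,,
P7,23,2,95,6,0.8,9,0.2,,,No
P7,24,1,89,5,1,,,,,
P7,25,2,61,6,0.79,10,0.21,,,No
P7,26,2,77,6,0.86,10,0.14,,,No
P8,1,2,17,4,0.6,5,0.4,,,No
P8,2,2,67,8,0.2,9,0.8,,,Yes
P8,3,1,<5,5,1,,,,,
P8,4,1,<5,4,1,,,,,
P8,5,1,37,5,1,,,,,
P8,6,1,59,3,1,,,,,
P8,7,3,97,6,0.49,6,0.4753,10,0.39,No
P8,8,1,62,6,1,,,,,
P8,9,1,96,5,1,,,,,
P8,10,1,98,8,1,,,,,
P8,11,2,37,5,0.33,6,0.67,,,Yes
P8,12,1,96,7,1,,,,,
P8,13,1,80,7,1,,,,,
P8,14,1,37,5,1,,,,,
P8,15,2,59,4,0.57,6,0.43,,,No
P8,16,1,low level,4,1,,,,,
P8,17,2,61,5,0.75,7,0.25,,,No
P8,18,2,58,4,0.47,8,0.53,,,Yes
P8,19,1,46,5,1,,,,,
P8,20,1,70,10,1,,,,,
P8,21,3,98,5,0.29,7,0.44,8,0.27,Yes
P8,22,1,96,8,1,,,,,
P8,23,2,80,4,0.27,6,0.73,,,Yes
P8,24,2,96,5,0.23,7,0.77,,,Yes
P8,25,1,98,4,1,,,,,
P8,26,2,98,6,0.51,7,0.49,,,No
P8,27,2,99,5,0.54,6,0.46,,,No
P16,1,1,14,4,1,,,,,
P16,2,1,84,6,1,,,,,
P16,3,1,91,7,1,,,,,
P16,4,1,u.m,7,1,,,,,
P16,5,3,82,4,0.39,5,0.23,8,0.38,No
P16,6,1,95,5,1,,,,,
P16,7,2,62,6,0.73,7,0.27,,,No
P16,8,1,94,6,1,,,,,
P16,9,2,67,6,0.37,7,0.63,,,Yes
P16,10,1,92,7.5,1,,,,,
P16,11,2,57,6,0.17,8.5,0.83,,,Yes
P16,12,1,43,6,1,,,,,
P16,13,2,38,6.5,0.43,7.5,0.57,,,Yes
P16,14,1,89,6,1,,,,,
P16,15,1,u.m,2,1,,,,,
P16,16,2,23,5,0.53,7,0.47,,,No
P16,17,1,46,9,1,,,,,
P16,18,1,72,7,1,,,,,
P16,19,1,34,7,1,,,,,
P16,20,2,67,3,0.54,7,0.46,,,No
P16,21,1,82,6,1,,,,,
P16,22,1,31,4,1,,,,,
P16,23,2,76,6,0.57,8,0.43,,,No
P16,24,1,44,6,1,,,,,
P16,25,1,52,7,1,,,,,
P16,26,1,27,5,1,,,,,
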