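product_id,cell_id,patient_id,bp5,bp3,size_bp,nd1_dloop_pct,nd4_dloop_pct,flank5,flank3,repeat_annotation
1X,1,P3,3270,11195,7924,75.1,39.8,GGTAATCGCATAAAACTTAAAAC,GGCACATACTTCCTATT,no repeat
2X,2,P3,3263,12299,9035,90.5,86.9,TAATCGCATAAAAC,AGGCCCCAAAAATTTT,no repeat
2Y,2,P3,4351,13924,9572,,,TATGAGAATCGAACCC,CCCTAGCATCACACACC,no repeat
2Z,2,P3,3326,11668,8341,,,CATACCCATGGCCAACCTCCT,CTCCTCCAAACCCCC,5bp perfect repeat
3X,3,P3,5791,12302,6510,19.9,93.8,GGCAGGTTTGAAGCTGCTTCTTCG,GCCCCAAAAATTTTGGT,no repeat
4X,4,P3,5786,13238,7451,7.9,69.3,CAGGTTTGAAGCTGCTT,TCGTAGCCTTCTCCAC,no repeat
4Y,4,P3,8591,11464,2872,,,GGCCTACCCGCCGCAGTACT,GCCGCAGTACTCTTAAAACTAGGC,11bp perfect repeat
5X,5,P3,3914,12299,8384,19.9,91.9,CCCCCTTCGACCTTGCCGAAGG,AGGCCCCAAAAATTTT,no repeat
6X,6,P3,3263,11493,8229,24.7,80.2,TAATCGCATAAAAC,ATAAAACGCCTCACACTCATT,7bp perfect repeat
7X,7,P3,4351,12111,7759,4.0,99.1,TAGGACTATGAGAATCGAACCC,CCCCGACATCATTACCGG,no repeat
8X,8,P3,5787,13924,8136,7.5,95.4,CAGGTTTGAAGCTGCTTC,CCCTAGCATCACACACCG,no repeat
9X,9,P3,4376,13923,9546,18.4,99.5,GAATCCAAAATTCTCCG,CCCTAGCATCACACACCG,no repeat
9Y,9,P3,5786,13238,7451,,,CAGGTTTGAAGCTGCTT,TCGTAGCCTTCTCCAC,no repeat
9Z,9,P3,3260,12299,9038,,,GCCCGGTAATCGCATAA,AGGCCCCAAAAATTTTGGT,no repeat
10X,10,P3,5825,13923,8097,0.0,96.6,AAAATCACCTCGGAGC,CCCTAGCATCACACACC,no repeat
11X,11,P6,6226,12107,5880,14.2,94.6,TTCTGACTCTTACCCCTCCCTC,TCCCTCAACCCCGAC,6bp perfect repeat
11Y,11,P6,8482,13460,4977,,,CCACCTACCTCCCTCACCA,ACCTCCCTCACCATTGGCAGCCTAGCA,13bp perfect repeat
12X,12,P6,7809,14001,6191,8.8,92.3,TCCTGCCCGCCATCATCCTAGACCT,TCCTAGACCTAACCTGACTAGAAAA,10bp perfect repeat
12Y,12,P6,6226,12107,5880,,,TTCTGACTCTTACCCCTCCCTC,TCCCTCAACCCCGAC,6bp perfect repeat
13X,13,P11,6341,14005,7663,95.6,33.7,GCCTCCGTAGACCTAACC,TAGACCTAACCTGACTAGAAAAGCTA,11bp perfect repeat
13Y,13,P11,5787,13923,8135,,,CAGGTTTGAAGCTGCTTC,CCCTAGCATCACACACCG,no repeat
14X,14,P11,6880,13457,6576,18.6,97.4,TTTAGCTGACTCGCCAC,CCATTGGCAGCCTAGCATT,no repeat
15X,15,P11,5787,13924,8136,14.9,67.2,CAGGTTTGAAGCTGCTTC,CCTAGCATCACACACCG,no repeat
16X,16,P11,6341,14005,7663,13.6,94.2,GCCTCCGTAGACCTAACC,TAGACCTAACCTGACTAGAAAAGCTA,11bp perfect repeat
17X,17,P11,5788,13922,8133,10.3,94.6,CAGGTTTGAAGCTGCTTCT,TTCTACCCTAGCATCACACACC,4bp perfect repeat
18X,18,P14,3270,11195,7924,0.0,82.8,GGTAATCGCATAAAACTTAAAAC,GGCACATACTTCCTATT,no repeat
19X,19,P14,5788,13923,8134,0.0,85.3,GGCAGGTTTGAAGCTGCTTCT,CCCTAGCATCACACACC,no repeat
19Y,19,P14,4351,12111,7759,,,TAGGACTATGAGAATCGAACCC,CCCCGACATCATTACCGG,no repeat
20X,20,P14,5787,13923,8135,13.0,45.1,CAGGTTTGAAGCTGCTTC,CCCTAGCATCACACACCG,no repeat
21X,21,P14,6798,14269,7470,4.1,95.7,TTTACAGTAGGAATAGACG,CGAATCAACCCTGACCCCTCT,no repeat
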