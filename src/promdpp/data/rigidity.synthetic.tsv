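# property_name: rigidity
# step_size: 4
# units: dimensionless
# source: SYNTHETIC STAND-IN: tetranucleotide rigidity source unavailable offline; mean over the 3 dinucleotide steps of 10/deformability (Olson et al. 1998)
AAAA	3.4483
AAAC	3.7481
AAAG	3.8862
AAAT	4.3822
AACA	2.9388
AACC	3.1451
AACG	2.8742
AACT	4.186
AAGA	3.4775
AAGC	3.5701
AAGG	3.2832
AAGT	4.186
AATA	3.7619
AATC	3.9735
AATG	3.5729
AATT	4.3822
ACAA	2.9388
ACAC	3.2387
ACAG	3.3767
ACAT	3.8727
ACCA	2.3359
ACCC	2.5422
ACCG	2.2712
ACCT	3.583
ACGA	2.4655
ACGC	2.5581
ACGG	2.2712
ACGT	3.174
ACTA	3.5657
ACTC	3.7773
ACTG	3.3767
ACTT	4.186
AGAA	3.4775
AGAC	3.7773
AGAG	3.9153
AGAT	4.4114
AGCA	2.7608
AGCC	2.9671
AGCG	2.6961
AGCT	4.0079
AGGA	2.8745
AGGC	2.9671
AGGG	2.6802
AGGT	3.583
AGTA	3.5657
AGTC	3.7773
AGTG	3.3767
AGTT	4.186
ATAA	3.7619
ATAC	4.0617
ATAG	4.1997
ATAT	4.6958
ATCA	3.1642
ATCC	3.3705
ATCG	3.0996
ATCT	4.4114
ATGA	3.1642
ATGC	3.2568
ATGG	2.9699
ATGT	3.8727
ATTA	3.7619
ATTC	3.9735
ATTG	3.5729
ATTT	4.3822
CAAA	2.639
CAAC	2.9388
CAAG	3.0769
CAAT	3.5729
CACA	2.1295
CACC	2.3359
CACG	2.0649
CACT	3.3767
CAGA	2.6682
CAGC	2.7608
CAGG	2.4739
CAGT	3.3767
CATA	2.9526
CATC	3.1642
CATG	2.7636
CATT	3.5729
CCAA	2.036
CCAC	2.3359
CCAG	2.4739
CCAT	2.9699
CCCA	1.433
CCCC	1.6393
CCCG	1.3684
CCCT	2.6802
CCGA	1.5627
CCGC	1.6553
CCGG	1.3684
CCGT	2.2712
CCTA	2.6629
CCTC	2.8745
CCTG	2.4739
CCTT	3.2832
CGAA	2.1656
CGAC	2.4655
CGAG	2.6035
CGAT	3.0996
CGCA	1.449
CGCC	1.6553
CGCG	1.3843
CGCT	2.6961
CGGA	1.5627
CGGC	1.6553
CGGG	1.3684
CGGT	2.2712
CGTA	2.2539
CGTC	2.4655
CGTG	2.0649
CGTT	2.8742
CTAA	3.2658
CTAC	3.5657
CTAG	3.7037
CTAT	4.1997
CTCA	2.6682
CTCC	2.8745
CTCG	2.6035
CTCT	3.9153
CTGA	2.6682
CTGC	2.7608
CTGG	2.4739
CTGT	3.3767
CTTA	3.2658
CTTC	3.4775
CTTG	3.0769
CTTT	3.8862
GAAA	3.0396
GAAC	3.3394
GAAG	3.4775
GAAT	3.9735
GACA	2.5302
GACC	2.7365
GACG	2.4655
GACT	3.7773
GAGA	3.0688
GAGC	3.1614
GAGG	2.8745
GAGT	3.7773
GATA	3.3532
GATC	3.5648
GATG	3.1642
GATT	3.9735
GCAA	2.3229
GCAC	2.6227
GCAG	2.7608
GCAT	3.2568
GCCA	1.7199
GCCC	1.9262
GCCG	1.6553
GCCT	2.9671
GCGA	1.8496
GCGC	1.9421
GCGG	1.6553
GCGT	2.5581
GCTA	2.9497
GCTC	3.1614
GCTG	2.7608
GCTT	3.5701
GGAA	2.4366
GGAC	2.7365
GGAG	2.8745
GGAT	3.3705
GGCA	1.7199
GGCC	1.9262
GGCG	1.6553
GGCT	2.9671
GGGA	1.8336
GGGC	1.9262
GGGG	1.6393
GGGT	2.5422
GGTA	2.5248
GGTC	2.7365
GGTG	2.3359
GGTT	3.1451
GTAA	3.1278
GTAC	3.4277
GTAG	3.5657
GTAT	4.0617
GTCA	2.5302
GTCC	2.7365
GTCG	2.4655
GTCT	3.7773
GTGA	2.5302
GTGC	2.6227
GTGG	2.3359
GTGT	3.2387
GTTA	3.1278
GTTC	3.3394
GTTG	2.9388
GTTT	3.7481
TAAA	2.828
TAAC	3.1278
TAAG	3.2658
TAAT	3.7619
TACA	2.3185
TACC	2.5248
TACG	2.2539
TACT	3.5657
TAGA	2.8571
TAGC	2.9497
TAGG	2.6629
TAGT	3.5657
TATA	3.1415
TATC	3.3532
TATG	2.9526
TATT	3.7619
TCAA	2.2303
TCAC	2.5302
TCAG	2.6682
TCAT	3.1642
TCCA	1.6273
TCCC	1.8336
TCCG	1.5627
TCCT	2.8745
TCGA	1.757
TCGC	1.8496
TCGG	1.5627
TCGT	2.4655
TCTA	2.8571
TCTC	3.0688
TCTG	2.6682
TCTT	3.4775
TGAA	2.2303
TGAC	2.5302
TGAG	2.6682
TGAT	3.1642
TGCA	1.5136
TGCC	1.7199
TGCG	1.449
TGCT	2.7608
TGGA	1.6273
TGGC	1.7199
TGGG	1.433
TGGT	2.3359
TGTA	2.3185
TGTC	2.5302
TGTG	2.1295
TGTT	2.9388
TTAA	2.828
TTAC	3.1278
TTAG	3.2658
TTAT	3.7619
TTCA	2.2303
TTCC	2.4366
TTCG	2.1656
TTCT	3.4775
TTGA	2.2303
TTGC	2.3229
TTGG	2.036
TTGT	2.9388
TTTA	2.828
TTTC	3.0396
TTTG	2.639
TTTT	3.4483
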