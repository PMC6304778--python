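# synthetic barcode-block whitelist: 96 six-mers, pairwise Hamming distance >= 3
# generated deterministically (greedy packing); NOT a vendor barcode list
AAAGTA
AAATGG
AACCTT
AACGAC
AAGTAT
AATATC
ACATTC
ACCAAG
ACCCCA
ACCTGT
ACGACT
ACGGGC
ACTTAA
AGAACG
AGACGA
AGCTTA
AGGCCC
AGTGCT
ATAAAT
ATCACC
ATGAGG
ATGGAA
ATTCTA
ATTTGC
CAATTT
CACAGC
CAGATA
CAGCCG
CATGCA
CCATCG
CCCGAT
CCGCTT
CCTATG
CCTCGA
CGAAAA
CGATGC
CGCATT
CGCGCC
CGGGGA
CGGTCT
CGTCTC
CGTGAG
CTACTG
CTCCCT
CTCGGG
CTCTAA
CTGTTC
CTTAGT
GACACT
GACCAA
GACTTC
GAGGCC
GATAAG
GATGGT
GCAAGG
GCACCC
GCAGAA
GCCATA
GCCGCG
GCGAAC
GCGTGA
GCTGTC
GCTTCT
GGAATC
GGACAT
GGATCA
GGCTGG
GGGAGT
GGGCTA
GGTCCG
GGTTAC
GTCGTT
GTGACA
GTGCGC
GTGTAG
TAATAC
TACGGA
TAGCGT
TAGTCA
TATCCC
TATTTG
TCACTA
TCCTCC
TCTAGC
TCTCAT
TGAGGT
TGCACA
TGCCAG
TGGGTG
TGTTGA
TTAGAG
TTATCT
TTCCTC
TTGATT
TTTAAA
TTTCGG
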