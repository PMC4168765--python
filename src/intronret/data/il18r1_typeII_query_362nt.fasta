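>IL18R1_typeII_query exons 7-8 coding sequence plus first 60 nt of intron 8-9 (362 nt)
GACTCCAGAAGGCAAATGGCATGCTTCAAAAGTATTGAGAATTGAAAATATTGGTGAAAG
CAATCTAAATGTTTTATATAATTGCACTGTGGCCAGCACGGGAGGCACAGACACCAAAAG
CTTCATCTTGGTGAGAAAAGCAGACATGGCTGATATCCCAGGCCACGTCTTCACAAGAGG
AATGATCATAGCTGTTTTGATCTTGGTGGCAGTAGTGTGCCTAGTGACTGTGTGTGTCAT
TTATAGAGTTGACTTGGTTCTATTTTATAGACATTTAACGAGAAGAGATGAAACATTAAC
AGGTAACACATATAATGCTGGAATTTCTTACCTTATGTTCTCATTAAGAAATCAGATAAA
TA
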