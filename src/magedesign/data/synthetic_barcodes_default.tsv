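id	left	right
bc_01	CGCGACGTATACCGTGATAT	AACCGGATATCGCTAGCGCA
bc_02	GCGACGCACCTATGTTTATA	ATGAAGATTGCGCTACCTCG
bc_03	ACCCGTGGTCACACCATGAA	TAATCGGGGAGTATGTGGGT
bc_04	CCTACGACCCCGCATTGTAG	GAACTGCTGAAGCTCTTGAT
bc_05	TGGCCCCGAAAACGTCTTGG	CAGGAAGCATGAGTTCGAGC
bc_06	GATGATGCCGAAGCCCCCTT	AAGTCTTCCAGTGGTTTCCG
bc_07	CCGCGTCGGCTTTGGCATTA	CTATTGTCGCATAGTGATTC
bc_08	ATATCTGAGATGGTAGGTAC	CACATAAACGACACCGCGGC
bc_09	ATGTGTGCACCCACTACCCA	CGGCCAGCTAAAGGTGCTAG
bc_10	TCTAGGACGTCATTGGAATA	ATTACCGGTAGAAATCGGGC
bc_11	GAGATGTCAAACCAGTCAAC	GAGAACAGTGTTAGCTTTAG
bc_12	TTTTTAACAGTAGGGCGGTA	CTTTGGAGTATTCTGTTGAC
bc_13	TGATGGCCGCTATCTTGTCG	GCACAGGAATCAGTCAAGAC
bc_14	CGTTGATCCCCTAAAGTTCA	TCATACACCGTTGCTAAAGC
bc_15	CACCAACGTAAGACCTGGCC	AACGGCAGTTGTACGGCTAT
bc_16	CTTACTATGGTGCCACTATT	TGCCCCATTTGATGATACTG
bc_17	AGGTGTCCCTAGTGTGCATG	ATGGCGAGCGAGTAACAATG
bc_18	GCTGTTTGGTTACGTCACGT	GCATTAGCTACCACCAACTG
bc_19	TACTCCGCGCCTGTCGACTT	CAATGGTGGTTCGCTAGAAC
bc_20	GCCATCTTAGGTTTATCAAC	CTCTTTATGACTCTGGCAAT
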