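>adan_nt synthetic back-translation (one fixed codon per residue); not the genomic coding sequence
GAAGCTTCTAATTGTTTTGCTATTAGACATTTTGAAAATAAATTTGCTGTTGAAACTTTGATTTGTTTTAATTTGTTTTTGAATTCTCAAGAAAAACATTAT
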