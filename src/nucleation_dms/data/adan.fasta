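>adan 34-residue stop-loss extension peptide
EASNCFAIRHFENKFAVETLICFNLFLNSQEKHY
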