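variant_class	count
nonsyn_snv	1831
indel	90
splice_site	7
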