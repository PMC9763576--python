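# instruments without usable outcome-GWAS information
rs7422339
rs2851391
rs12780845
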