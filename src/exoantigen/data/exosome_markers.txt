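# Canonical exosome-enriched marker proteins used for compartment QC.
CD81
CD9
FLOT1
FLOT2
PDCD6IP
SDCBP
TSG101
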