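# Endomembrane proteins expected to be underrepresented in exosomes.
CANX
CYC1
GOLGA2
HSP90B1
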