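orf	start	end
ORF1	908	1921
ORF2	1990	5814
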