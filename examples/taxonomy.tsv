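root	root	no rank	root
bacteria	root	domain	Bacteria
enterobacteria	bacteria	family	Enterobacteriaceae
ecoli_ref	enterobacteria	strain	Escherichia coli K-12
distant_ref	enterobacteria	strain	Escherichia fergusonii
bacteroides_ref	bacteria	species	Bacteroides vulgatus
rare_ref	bacteria	species	Eggerthella lenta
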