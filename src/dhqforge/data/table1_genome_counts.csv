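source,category,n_genomes
Bacteria,type_I_only,60
Bacteria,type_II_only,306
Bacteria,both,25
Archaea,type_I,43
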