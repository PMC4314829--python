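quantity,count
total,459
type_I,128
type_II,331
archaeal_type_I,43
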