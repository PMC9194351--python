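# Vaccine hesitancy phrases. Partial reconstruction around the quoted
# examples; edit freely.
will not take
won't take
wont take
refuse the vaccine
not taking the vaccine
rushed
adverse reaction
side effect
experimental
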