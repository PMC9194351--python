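# Vaccine misinformation phrases. Partial reconstruction around the quoted
# examples and the subtopic families; edit freely.
change dna
changes dna
alter your dna
alters your dna
change your dna
microchip
micro chip
sterilize
sterilis
aborted cells
aborted fetal
depopulation
genocid
plandemic
mark of the beast
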