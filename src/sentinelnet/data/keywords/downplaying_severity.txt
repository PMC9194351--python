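# Phrases associated with downplaying COVID-19 severity. Partial
# reconstruction around the quoted examples; edit freely.
lower than flu
mild
overcount
over count
inflated
false positive
just the flu
only 6%
only six percent
comorbidit
99% survival
99 percent survival
survival rate of 99
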