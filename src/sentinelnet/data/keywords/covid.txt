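# COVID gate: a tweet is COVID-related if it contains any of these substrings
covid
coronavirus
sars-cov
pandemic
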