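fatality rate
death rate
survival rate
death numbers
covid-19 death
covid death
covid19 death
died from covid
died of covid
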