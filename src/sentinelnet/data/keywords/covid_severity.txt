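# COVID-19 severity phrases. Partial reconstruction: the quoted seed phrases
# plus closely related incidence/mortality wording; edit freely.
death rate
fatality rate
survival rate
confirmed cases
case spike
case count
death count
death toll
death numbers
covid-19 death
covid death
covid19 death
died from covid
died of covid
hospitalization rate
mortality rate
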