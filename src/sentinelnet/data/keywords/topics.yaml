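covid:
  file: covid.txt
plandemic:
  file: plandemic.txt
  parent: covid
hydroxychloroquine:
  file: hydroxychloroquine.txt
  parent: covid
facemasks:
  file: facemasks.txt
  parent: covid
covid_mortality:
  file: covid_mortality.txt
  parent: covid
covid_severity:
  file: covid_severity.txt
  parent: covid
downplaying_severity:
  file: downplaying_severity.txt
  parent: covid_severity
vaccines:
  file: vaccines.txt
  parent: covid
vaccine_hesitancy:
  file: vaccine_hesitancy.txt
  parent: vaccines
vaccine_misinformation:
  file: vaccine_misinformation.txt
  parent: vaccines
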