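; Starter COVID-19 keyword/hashtag list (the full operational list is a run
; input supplied with --covid-keywords; this bundled list backs the tests
; and the synthetic generator).
covid
covid-19
covid19
#covid19
#covid_19
coronavirus
#coronavirus
corona virus
sars-cov-2
sarscov2
pandemic
epidemic
quarantine
#quarantine
lockdown
#lockdown
social distancing
#socialdistancing
self-isolation
ventilator
n95
ppe
face mask
#facemask
hand sanitizer
#stayhome
stay at home order
flatten the curve
#flattenthecurve
herd immunity
contact tracing
covid vaccine
#covidvaccine
pcr test
antigen test
asymptomatic
superspreader
#wearamask
long covid
covid variant
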