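# name: neonatal ponderal index reference by sex and completed gestational week
# units: g*100/cm^3
index_kind,sex,ga_weeks,mean,sd
PI,male,32,2.43,0.26
PI,male,33,2.41,0.20
PI,male,34,2.35,0.19
PI,male,35,2.54,0.28
PI,male,36,2.64,0.59
PI,male,37,2.62,0.31
PI,male,38,2.70,0.34
PI,male,39,2.69,0.25
PI,male,40,2.73,0.42
PI,male,41,2.72,0.39
PI,male,42,2.79,0.18
PI,female,32,2.42,0.14
PI,female,33,2.35,0.26
PI,female,34,2.42,0.30
PI,female,35,2.61,0.72
PI,female,36,2.59,0.30
PI,female,37,2.66,0.42
PI,female,38,2.74,0.46
PI,female,39,2.72,0.29
PI,female,40,2.75,0.31
PI,female,41,2.76,0.35
PI,female,42,2.78,0.30
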