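# name: neonatal BMI reference by sex and completed gestational week
# units: kg/m2
index_kind,sex,ga_weeks,mean,sd
BMI,male,32,10.44,1.18
BMI,male,33,10.66,1.17
BMI,male,34,10.59,1.08
BMI,male,35,11.90,1.45
BMI,male,36,12.39,2.07
BMI,male,37,12.60,1.36
BMI,male,38,13.25,1.36
BMI,male,39,13.41,1.17
BMI,male,40,13.67,1.47
BMI,male,41,13.84,1.45
BMI,male,42,14.12,1.23
BMI,female,32,10.25,0.74
BMI,female,33,10.19,1.02
BMI,female,34,10.77,1.42
BMI,female,35,11.84,2.14
BMI,female,36,12.08,1.50
BMI,female,37,12.59,1.59
BMI,female,38,13.18,1.60
BMI,female,39,13.30,1.25
BMI,female,40,13.58,1.26
BMI,female,41,13.82,1.30
BMI,female,42,13.72,1.34
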