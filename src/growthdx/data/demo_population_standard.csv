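# name: synthetic-demo-population-standard
# citation: synthetic demonstration table generated by growthdx; not a published standard
sex,ga_weeks,location_g,scale_g
female,24.0,600.4,81.1
female,25.0,687.5,92.8
female,26.0,793.7,107.1
female,27.0,917.0,123.8
female,28.0,1055.5,142.5
female,29.0,1207.1,163.0
female,30.0,1369.9,184.9
female,31.0,1541.7,208.1
female,32.0,1720.7,232.3
female,33.0,1904.9,257.2
female,34.0,2092.1,282.4
female,35.0,2280.5,307.9
female,36.0,2468.1,333.2
female,37.0,2652.7,358.1
female,38.0,2832.5,382.4
female,39.0,3005.4,405.7
female,40.0,3169.5,427.9
female,41.0,3322.7,448.6
female,42.0,3463.0,467.5
female,43.0,3588.4,484.4
male,24.0,623.2,84.1
male,25.0,713.6,96.3
male,26.0,823.8,111.2
male,27.0,951.9,128.5
male,28.0,1095.6,147.9
male,29.0,1253.0,169.1
male,30.0,1421.9,192.0
male,31.0,1600.3,216.0
male,32.0,1786.1,241.1
male,33.0,1977.2,266.9
male,34.0,2171.6,293.2
male,35.0,2367.1,319.6
male,36.0,2561.8,345.8
male,37.0,2753.5,371.7
male,38.0,2940.1,396.9
male,39.0,3119.6,421.1
male,40.0,3289.8,444.1
male,41.0,3448.8,465.6
male,42.0,3594.5,485.3
male,43.0,3724.7,502.8
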