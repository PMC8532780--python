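residue,eps_iso,eps11,eps22,eps33,alpha,beta,gamma
Aib1,136.7,77.1,91.5,241.7,2.5,14.1,12.9
Pro2,133.6,47.7,125.4,227.6,,,
Aib3,120.3,63.5,75.0,222.3,7.0,14.8,28.7
Ala4,117.7,48.3,81.7,223.2,1.1,16.2,17.2
Aib5,125.7,68.2,78.4,230.5,4.3,13.1,31.3
Ala6,116.6,53.7,75.5,220.7,2.9,18.2,16.1
Gln7,119.7,56.8,76.0,226.3,4.6,18.2,30.1
Aib8,127.8,68.5,78.6,236.4,4.2,12.9,51.5
Val9,114.3,51.6,78.0,213.2,1.6,17.6,12.0
Aib10,127.8,69.0,81.4,233.1,3.1,14.6,48.0
Gly11,101.2,45.0,55.7,202.9,4.0,23.8,45.2
Leu12,116.5,48.7,77.1,223.8,4.1,18.8,36.7
Aib13,131.5,71.5,86.0,237.1,2.1,14.6,70.0
Pro14,131.0,50.8,118.5,223.7,,,
Val15,116.4,57.6,71.6,220.0,5.3,20.1,48.5
Aib16,125.8,62.9,83.4,231.1,1.6,10.9,17.8
Aib17,122.6,65.5,79.3,223.0,4.6,14.4,10.1
Glu18,115.8,56.7,73.1,217.5,4.9,20.8,13.9
Gln19,117.8,52.7,75.2,225.4,2.0,19.1,24.3
Phl20,112.0,56.9,65.8,213.3,5.4,19.9,15.8
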