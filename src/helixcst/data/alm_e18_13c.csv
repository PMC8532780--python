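residue,eps_iso,eps11,eps22,eps33,alpha,beta,gamma,eps_aniso
Aib1,178.0,102,181.9,250.0,1.2,4.8,1.4,5.9
Pro2,180.5,97.2,189.0,255.2,1.7,4.0,4.2,12.8
Aib3,180.2,100.3,187.0,253.4,1.2,2.6,1.4,10.2
Ala4,179.4,98.5,188.8,250.9,0.5,2.3,1.5,14.1
Aib5,180.0,101.0,183.0,256.0,1.2,1.8,2.2,4.5
Ala6,179.7,95.9,193.2,249.9,3.1,3.1,3.4,20.3
Gln7,178.1,97.0,189.0,248.2,0.3,2.0,1.7,16.4
Aib8,179.5,101.4,178.4,258.6,0.2,1.9,1.9,-1.6
Val9,179.1,96.8,187.0,253.5,0.6,0.8,0.9,11.9
Aib10,182.1,99.6,189.3,257.3,1.4,1.4,2.6,10.9
Gly11,171.7,94.4,166.8,253.8,2.2,3.0,2.3,-7.3
Leu12,180.9,97.3,198.7,246.8,0.8,4.2,0.8,26.6
Aib13,178.2,102.1,182.7,249.8,0.5,5.3,1.5,6.8
Pro14,179.1,94.4,190.0,252.8,0.7,1.3,3.0,16.4
Val15,177.9,97.9,182.9,253.0,0.3,2.2,0.7,7.4
Aib16,178.9,100.5,182.5,253.7,0.1,2.1,2.1,5.3
Aib17,179.2,98.7,188.6,250.5,1.5,3.8,2.9,14.0
Glu18,177.6,92.8,196.9,243.1,3.3,5.6,4.0,28.9
Gln19,179.2,95.6,186.8,255.2,1.8,3.8,3.1,11.4
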