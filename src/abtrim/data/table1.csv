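variant,Aβ49,Aβ46,Aβ43,Aβ40,Aβ48,Aβ45,Aβ42,Aβ38
WT-L,56.0,201.7,103.3,196.9,131.5,153.3,231.6,34.2
WT-H,26.3,176.3,121.0,191.8,91.2,180.9,232.0,23.7
S169L,3.7,52.7,-2.8,42.5,264.6,52.8,53.8,12.9
S170F,38.4,128.3,-2.8,67.9,-173.5,221.2,80.8,4.9
G378E,44.2,76.7,-5.5,21.6,112.2,88.9,19.2,1.3
F386S,41.4,222.9,140.9,41.2,634.8,180.1,43.3,4.3
A431E,NA,8.3,-8.8,8.8,NA,52.6,5.1,0.4
A434T,NA,0,-7.9,7.9,NA,9.2,9.4,0.3
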