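cultivar,species,region,season,mean,sd
Legacy,V. corymbosum,RA,spring,106.2,2.8
Ozarkblue,V. corymbosum,RA,spring,106.5,2.5
Misty,V. corymbosum,RA,spring,157.6,8.1
Star,V. corymbosum,RA,spring,99.1,2.4
Ochlochonee,V. ashei,RA,spring,127.3,7.9
Drapler,V. corymbosum,RA,spring,134.4,3.8
Bluecrop,V. corymbosum,RA,spring,127.8,4.2
Duke,V. corymbosum,RA,spring,82.8,11.6
Powderblue,V. ashei,RA,spring,161.2,2.8
O'neal,V. corymbosum,RA,spring,72.7,1.1
Chandler,V. corymbosum,RA,spring,123.8,2.1
Bluejay,V. corymbosum,RA,spring,127.3,5.4
Camellia,V. corymbosum,RA,spring,104.2,8.8
Goldtraube,V. corymbosum,RA,spring,114.2,3.2
Titan,V. ashei,RA,spring,153.2,2.6
Huron,V. corymbosum,RA,spring,75.5,2.2
Aurora,V. corymbosum,RA,spring,110.9,3.3
Liberty,V. corymbosum,RA,spring,117.9,14.8
Legacy,V. corymbosum,RB,spring,102.2,3.2
Ochlochonee,V. ashei,RB,spring,117.2,5.2
Drapler,V. corymbosum,RB,spring,55.2,1.8
Bluecrop,V. corymbosum,RB,spring,95.6,2.9
Duke,V. corymbosum,RB,spring,74.3,4.1
Powderblue,V. ashei,RB,spring,131.2,4.8
Chandler,V. corymbosum,RB,spring,83.0,9.4
Camellia,V. corymbosum,RB,spring,81.9,12.5
Bluegold,V. corymbosum,RB,spring,69.8,3.9
Alix blue,V. corymbosum,RC,spring,97.9,5.9
New hanover,V. corymbosum,RC,spring,92.7,4.1
Sunset blue,V. corymbosum,RC,spring,98.8,5.0
Gupton,V. corymbosum,RC,spring,96.6,5.2
Cipria,V. corymbosum,RC,spring,137.3,4.4
Legacy,V. corymbosum,RA,fall,64.3,1.2
Ozarkblue,V. corymbosum,RA,fall,78.9,3.3
Misty,V. corymbosum,RA,fall,177.6,6.2
Ochlochonee,V. ashei,RA,fall,217.9,3.2
Bluecrop,V. corymbosum,RA,fall,120.4,5.5
Duke,V. corymbosum,RA,fall,93.0,1.3
Chandler,V. corymbosum,RA,fall,166.5,2.6
Camellia,V. corymbosum,RA,fall,69.3,3.1
Goldtraube,V. corymbosum,RA,fall,154.1,5.7
Titan,V. ashei,RA,fall,40.8,1.3
Huron,V. corymbosum,RA,fall,39.6,1.8
Aurora,V. corymbosum,RA,fall,191.2,6.3
Liberty,V. corymbosum,RA,fall,157.3,1.6
Legacy,V. corymbosum,RA,winter,208.8,3.6
Misty,V. corymbosum,RA,winter,176.5,3.6
Star,V. corymbosum,RA,winter,170.1,1.6
Drapler,V. corymbosum,RA,winter,207.5,7.9
Bluecrop,V. corymbosum,RA,winter,131.0,2.1
Duke,V. corymbosum,RA,winter,118.6,4.3
Powderblue,V. ashei,RA,winter,219.7,6.1
O'neal,V. corymbosum,RA,winter,162.5,1.1
Chandler,V. corymbosum,RA,winter,199.4,5.9
Camellia,V. corymbosum,RA,winter,141.9,2.6
Goldtraube,V. corymbosum,RA,winter,152.5,3.5
Titan,V. ashei,RA,winter,272.8,4.0
Huron,V. corymbosum,RA,winter,192.2,3.9
Aurora,V. corymbosum,RA,winter,227.4,9.9
Liberty,V. corymbosum,RA,winter,176.9,6.0
Elliott,V. corymbosum,RA,winter,199.0,1.3
Patriot,V. corymbosum,RA,winter,155.5,5.2
Biloxi,V. corymbosum,RA,winter,150.7,3.9
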