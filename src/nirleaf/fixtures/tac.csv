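cultivar,species,region,season,mean,sd
Legacy,V. corymbosum,RA,spring,53.8,1.2
Ozarkblue,V. corymbosum,RA,spring,50.3,0.8
Misty,V. corymbosum,RA,spring,63.7,2.0
Star,V. corymbosum,RA,spring,46.5,1.5
Ochlochonee,V. ashei,RA,spring,62.8,0.8
Drapler,V. corymbosum,RA,spring,60.8,1.7
Bluecrop,V. corymbosum,RA,spring,57.0,1.2
Duke,V. corymbosum,RA,spring,39.3,1.5
Powderblue,V. ashei,RA,spring,65.5,1.0
O'neal,V. corymbosum,RA,spring,40.3,0.3
Chandler,V. corymbosum,RA,spring,55.8,0.8
Bluejay,V. corymbosum,RA,spring,59.1,1.7
Camellia,V. corymbosum,RA,spring,50.8,0.9
Goldtraube,V. corymbosum,RA,spring,50.2,3.3
Titan,V. ashei,RA,spring,63.1,1.3
Huron,V. corymbosum,RA,spring,41.7,1.3
Aurora,V. corymbosum,RA,spring,54.9,3.9
Liberty,V. corymbosum,RA,spring,61.9,4.4
Legacy,V. corymbosum,RB,spring,56.3,1.0
Ochlochonee,V. ashei,RB,spring,56.3,0.9
Drapler,V. corymbosum,RB,spring,34.5,2.2
Bluecrop,V. corymbosum,RB,spring,51.7,1.5
Duke,V. corymbosum,RB,spring,40.0,1.3
Powderblue,V. ashei,RB,spring,68.2,2.1
Chandler,V. corymbosum,RB,spring,43.0,3.7
Camellia,V. corymbosum,RB,spring,44.5,4.0
Bluegold,V. corymbosum,RB,spring,44.7,2.5
Alix blue,V. corymbosum,RC,spring,42.9,1.2
New hanover,V. corymbosum,RC,spring,43.0,1.9
Sunset blue,V. corymbosum,RC,spring,48.6,4.6
Gupton,V. corymbosum,RC,spring,46.4,3.8
Cipria,V. corymbosum,RC,spring,56.0,5.0
Legacy,V. corymbosum,RA,fall,34.4,1.3
Ozarkblue,V. corymbosum,RA,fall,43.1,2.7
Misty,V. corymbosum,RA,fall,99.6,3.3
Ochlochonee,V. ashei,RA,fall,101.1,1.4
Bluecrop,V. corymbosum,RA,fall,55.6,1.8
Duke,V. corymbosum,RA,fall,47.6,1.7
Chandler,V. corymbosum,RA,fall,92.1,0.9
Camellia,V. corymbosum,RA,fall,39.2,1.2
Goldtraube,V. corymbosum,RA,fall,86.2,1.2
Titan,V. ashei,RA,fall,23.2,1.1
Huron,V. corymbosum,RA,fall,22.6,0.7
Aurora,V. corymbosum,RA,fall,100.0,2.6
Liberty,V. corymbosum,RA,fall,23.3,1.6
Legacy,V. corymbosum,RA,winter,81.4,0.7
Misty,V. corymbosum,RA,winter,72.6,1.9
Star,V. corymbosum,RA,winter,76.4,0.9
Drapler,V. corymbosum,RA,winter,107.8,3.8
Bluecrop,V. corymbosum,RA,winter,61.1,2.2
Duke,V. corymbosum,RA,winter,61.0,1.8
Powderblue,V. ashei,RA,winter,115.8,3.5
O'neal,V. corymbosum,RA,winter,66.7,0.9
Chandler,V. corymbosum,RA,winter,107.3,0.9
Camellia,V. corymbosum,RA,winter,62.2,1.5
Goldtraube,V. corymbosum,RA,winter,70.6,2.1
Titan,V. ashei,RA,winter,124.8,2.5
Huron,V. corymbosum,RA,winter,113.4,3.1
Aurora,V. corymbosum,RA,winter,120.0,1.2
Liberty,V. corymbosum,RA,winter,73.3,1.7
Elliott,V. corymbosum,RA,winter,78.2,0.9
Patriot,V. corymbosum,RA,winter,64.5,1.7
Biloxi,V. corymbosum,RA,winter,62.2,1.5
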