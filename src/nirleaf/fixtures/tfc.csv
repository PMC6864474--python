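cultivar,species,region,season,mean,sd
Legacy,V. corymbosum,RA,spring,181.3,6.2
Ozarkblue,V. corymbosum,RA,spring,177.7,2.9
Misty,V. corymbosum,RA,spring,269.1,7.4
Star,V. corymbosum,RA,spring,97.4,3.9
Ochlochonee,V. ashei,RA,spring,181.1,7.9
Drapler,V. corymbosum,RA,spring,204.6,20.6
Bluecrop,V. corymbosum,RA,spring,198.1,9.8
Duke,V. corymbosum,RA,spring,79.6,9.7
Powderblue,V. ashei,RA,spring,248.8,20.4
O'neal,V. corymbosum,RA,spring,111.3,4.4
Chandler,V. corymbosum,RA,spring,119.2,3.5
Bluejay,V. corymbosum,RA,spring,184.5,5.4
Camellia,V. corymbosum,RA,spring,79.0,6.5
Goldtraube,V. corymbosum,RA,spring,110.7,4.9
Titan,V. ashei,RA,spring,244.2,7.5
Huron,V. corymbosum,RA,spring,103.0,5.6
Aurora,V. corymbosum,RA,spring,103.4,4.2
Liberty,V. corymbosum,RA,spring,78.8,5.8
Legacy,V. corymbosum,RB,spring,113.0,2.9
Ochlochonee,V. ashei,RB,spring,67.7,2.9
Drapler,V. corymbosum,RB,spring,71.0,6.2
Bluecrop,V. corymbosum,RB,spring,73.3,3.9
Duke,V. corymbosum,RB,spring,108.9,5.1
Powderblue,V. ashei,RB,spring,72.2,5.1
Chandler,V. corymbosum,RB,spring,74.9,4.0
Camellia,V. corymbosum,RB,spring,45.2,2.3
Bluegold,V. corymbosum,RB,spring,94.2,3.5
Alix blue,V. corymbosum,RC,spring,88.8,5.2
New hanover,V. corymbosum,RC,spring,96.2,6.9
Sunset blue,V. corymbosum,RC,spring,92.5,8.4
Gupton,V. corymbosum,RC,spring,97.3,4.8
Cipria,V. corymbosum,RC,spring,129.2,4.0
Legacy,V. corymbosum,RA,fall,60.5,1.4
Ozarkblue,V. corymbosum,RA,fall,59.2,2.9
Misty,V. corymbosum,RA,fall,163.7,10.0
Ochlochonee,V. ashei,RA,fall,192.7,4.5
Bluecrop,V. corymbosum,RA,fall,96.4,4.0
Duke,V. corymbosum,RA,fall,71.3,2.2
Chandler,V. corymbosum,RA,fall,133.9,4.4
Camellia,V. corymbosum,RA,fall,47.3,2.0
Goldtraube,V. corymbosum,RA,fall,115.1,4.4
Titan,V. ashei,RA,fall,47.5,4.6
Huron,V. corymbosum,RA,fall,41.2,4.8
Aurora,V. corymbosum,RA,fall,141.0,5.9
Liberty,V. corymbosum,RA,fall,50.0,4.6
Legacy,V. corymbosum,RA,winter,128.1,3.7
Misty,V. corymbosum,RA,winter,143.0,4.6
Star,V. corymbosum,RA,winter,125.1,2.4
Drapler,V. corymbosum,RA,winter,156.0,2.3
Bluecrop,V. corymbosum,RA,winter,86.4,2.3
Duke,V. corymbosum,RA,winter,87.5,3.2
Powderblue,V. ashei,RA,winter,189.1,6.0
O'neal,V. corymbosum,RA,winter,106.2,2.4
Chandler,V. corymbosum,RA,winter,156.7,7.6
Camellia,V. corymbosum,RA,winter,101.4,2.2
Goldtraube,V. corymbosum,RA,winter,118.1,5.7
Titan,V. ashei,RA,winter,242.5,6.9
Huron,V. corymbosum,RA,winter,133.8,6.0
Aurora,V. corymbosum,RA,winter,150.8,6.6
Liberty,V. corymbosum,RA,winter,126.4,4.2
Elliott,V. corymbosum,RA,winter,131.9,4.1
Patriot,V. corymbosum,RA,winter,89.6,5.6
Biloxi,V. corymbosum,RA,winter,96.0,3.1
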