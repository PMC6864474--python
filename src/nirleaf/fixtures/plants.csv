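cultivar,species,n_plants,months,berries_present
Biloxi,V. corymbosum,1,December,
New hanover,V. corymbosum,1,May,
Camellia,V. corymbosum,2,May;September;December,
O'neal,V. corymbosum,1,May;December,
Misty,V. corymbosum,1,May;September;December,
Alix blue,V. corymbosum,1,May,
Star,V. corymbosum,1,May;December,
Gupton,V. corymbosum,1,May,
Cipria,V. corymbosum,1,May,
Goldtraube,V. corymbosum,1,May;September;December,
Legacy,V. corymbosum,2,May;September;December,
Ozarkblue,V. corymbosum,1,May;September,
Bluegold,V. corymbosum,1,May,
Drapler,V. corymbosum,2,May;December,
Chandler,V. corymbosum,2,May;September;December,
Liberty,V. corymbosum,1,May;September;December,
Bluecrop,V. corymbosum,2,May;September;December,
Sunset blue,V. corymbosum,1,May,
Duke,V. corymbosum,2,May;September;December,
Patriot,V. corymbosum,1,December,
Bluejay,V. corymbosum,1,May,
Huron,V. corymbosum,1,May;September;December,
Aurora,V. corymbosum,1,May;September;December,
Elliott,V. corymbosum,1,December,
Titan,V. ashei,1,May;September;December,
Ochlochonee,V. ashei,2,May;September,
Powderblue,V. ashei,2,May;December,
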