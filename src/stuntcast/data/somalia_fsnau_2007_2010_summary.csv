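zone,region,n_clusters,n_examined,n_stunted
North East (Puntland),Bari,9,756,201
North East (Puntland),Mudug,61,6188,804
North East (Puntland),Nugaal,24,1673,383
North West (Somaliland),Awdal,26,862,7
North West (Somaliland),Sanaag,14,412,3
North West (Somaliland),Sool,3,142,18
North West (Somaliland),Togdheer,12,673,362
North West (Somaliland),Woqooyi Galbeed,23,2465,1378
South Central,Bakool,75,3534,1150
South Central,Banadir,1,51,0
South Central,Bay,98,5568,2133
South Central,Galgaduud,77,5831,1908
South Central,Gedo,111,6985,1999
South Central,Hiraan,142,10743,2260
South Central,Juba Dhexe,77,5253,2734
South Central,Juba Hoose,71,5560,1553
South Central,Shabelle Dhexe,101,7650,2414
South Central,Shabelle Hoose,141,9432,3432
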