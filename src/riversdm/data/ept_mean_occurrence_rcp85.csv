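species,p_t1,p_t2,delta_t2_pct,p_t3,delta_t3_pct
Rhithrogena loyolaea,0.0918,0.0655,-28.6,0.044,-52.1
Protonemura brevistyla,0.0886,0.0693,-21.8,0.0515,-41.9
Rhithrogena puthzi,0.1794,0.1492,-16.8,0.1216,-32.2
Rhithrogena alpestris,0.1685,0.141,-16.3,0.1167,-30.8
Protonemura nimborum,0.0833,0.0704,-15.5,0.0607,-27.2
Rhyacophila tristis,0.4437,0.3828,-13.7,0.3264,-26.4
Ecdyonurus picteti,0.1525,0.1308,-14.2,0.1124,-26.3
Drusus discolor,0.1182,0.1019,-13.8,0.088,-25.6
Habrophlebia lauta,0.1343,0.1089,-18.9,0.1062,-20.9
Nemoura minima,0.184,0.1657,-9.9,0.151,-17.9
Nemoura mortoni,0.3169,0.2902,-8.4,0.2629,-17.1
Rhyacophila torrentium,0.1949,0.1786,-8.4,0.1615,-17.1
Baetis alpinus,0.6686,0.6171,-7.7,0.5673,-15.2
Brachyptera risi,0.3063,0.2954,-3.6,0.2687,-12.3
Ecdyonurus venosus,0.2531,0.2381,-5.9,0.2227,-12.0
Halesus digitatus,0.2599,0.2396,-7.8,0.2288,-11.9
Epeorus alpicola,0.1348,0.127,-5.8,0.122,-9.5
Capnioneura nemuroides,0.1386,0.1329,-4.1,0.126,-9.1
Allogamus auricollis,0.475,0.455,-4.2,0.4413,-7.1
Ecdyonurus helveticus,0.3717,0.3579,-3.7,0.3466,-6.8
Ecdyonurus torrentis,0.0702,0.0635,-9.6,0.0667,-5.1
Baetis lutheri,0.2661,0.2709,1.8,0.2555,-4.0
Isoperla grammatica,0.1798,0.1768,-1.6,0.1736,-3.4
Odontocerum albicorne,0.2233,0.2198,-1.6,0.216,-3.3
Chloroperla susemicheli,0.134,0.1301,-2.9,0.1297,-3.2
Amphinemura sulcicollis,0.2848,0.2834,-0.5,0.2761,-3.1
Rhithrogena semicolorata,0.3744,0.3771,0.7,0.3631,-3.0
Isoperla rivulorum,0.0935,0.0906,-3.1,0.0923,-1.3
Protonemura lateralis,0.2695,0.2714,0.7,0.2705,0.4
Potamophylax cingulatus,0.3117,0.3166,1.6,0.3168,1.6
Habroleptoides confusa,0.2448,0.2402,-1.9,0.25,2.1
Perla grandis,0.1356,0.135,-0.5,0.1389,2.4
Baetis muticus,0.4266,0.437,2.5,0.4438,4.1
Centroptilum luteolum,0.1422,0.1415,-0.5,0.1516,6.6
Baetis rhodani,0.8408,0.8779,4.4,0.9062,7.8
Epeorus assimilis,0.2502,0.2597,3.8,0.277,10.7
Paraleptophlebia submarginata,0.1543,0.1617,4.8,0.1816,17.7
Hydropsyche siltalai,0.2047,0.2286,11.7,0.2535,23.8
Serratella ignita,0.1459,0.1706,16.9,0.1815,24.5
Ephemera danica,0.1199,0.1455,21.4,0.1859,55.1
Philopotamus ludificatus,0.0956,0.1307,36.7,0.1783,86.5
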