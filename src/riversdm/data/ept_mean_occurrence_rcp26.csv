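species,p_t1,p_t2,delta_t2_pct,p_t3,delta_t3_pct
Rhithrogena loyolaea,0.094,0.0846,-10.0,0.0862,-8.2
Protonemura brevistyla,0.0896,0.0846,-5.6,0.0849,-5.2
Nemoura minima,0.19,0.1791,-5.8,0.1817,-4.4
Capnioneura nemuroides,0.1448,0.1376,-5.0,0.1391,-3.9
Serratella ignita,0.1448,0.145,0.1,0.1395,-3.7
Rhyacophila tristis,0.4437,0.4294,-3.2,0.4346,-2.0
Allogamus auricollis,0.48,0.4714,-1.8,0.4716,-1.8
Rhithrogena puthzi,0.1809,0.1743,-3.6,0.1778,-1.7
Brachyptera risi,0.3079,0.3025,-1.8,0.3034,-1.5
Habrophlebia lauta,0.1373,0.13,-5.3,0.1352,-1.5
Protonemura nimborum,0.0839,0.0815,-2.9,0.0829,-1.3
Halesus digitatus,0.262,0.2556,-2.5,0.2589,-1.2
Odontocerum albicorne,0.2252,0.2224,-1.2,0.2227,-1.1
Baetis lutheri,0.268,0.2666,-0.5,0.2656,-0.9
Isoperla grammatica,0.1794,0.1785,-0.5,0.178,-0.8
Perla grandis,0.1375,0.1357,-1.3,0.1364,-0.8
Potamophylax cingulatus,0.3117,0.3105,-0.4,0.3092,-0.8
Amphinemura sulcicollis,0.2854,0.2834,-0.7,0.2834,-0.7
Baetis alpinus,0.6667,0.6578,-1.3,0.6625,-0.6
Rhithrogena semicolorata,0.3759,0.3749,-0.3,0.3748,-0.3
Baetis muticus,0.4288,0.4272,-0.4,0.4279,-0.2
Centroptilum luteolum,0.1444,0.143,-1.0,0.1441,-0.2
Ecdyonurus venosus,0.2512,0.2493,-0.7,0.2508,-0.2
Ecdyonurus picteti,0.1533,0.1508,-1.7,0.1532,-0.1
Nemoura mortoni,0.3181,0.3138,-1.3,0.3185,0.1
Chloroperla susemicheli,0.1348,0.1333,-1.1,0.1353,0.3
Rhithrogena alpestris,0.1683,0.1663,-1.2,0.169,0.4
Habroleptoides confusa,0.245,0.2437,-0.5,0.2463,0.5
Drusus discolor,0.1194,0.1165,-2.4,0.1201,0.6
Ecdyonurus helveticus,0.3697,0.3699,0.0,0.3727,0.8
Epeorus assimilis,0.247,0.2499,1.2,0.2491,0.8
Baetis rhodani,0.8386,0.8494,1.3,0.8481,1.1
Hydropsyche siltalai,0.2005,0.2061,2.8,0.2032,1.3
Paraleptophlebia submarginata,0.1554,0.1562,0.5,0.1575,1.3
Protonemura lateralis,0.2696,0.2708,0.4,0.2734,1.4
Rhyacophila torrentium,0.1942,0.197,1.4,0.1973,1.6
Epeorus alpicola,0.1352,0.1341,-0.8,0.1379,2.0
Isoperla rivulorum,0.0933,0.0952,2.0,0.0956,2.4
Ecdyonurus torrentis,0.0709,0.0696,-1.8,0.0727,2.6
Ephemera danica,0.1214,0.1265,4.2,0.1255,3.4
Philopotamus ludificatus,0.093,0.0991,6.6,0.0983,5.7
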