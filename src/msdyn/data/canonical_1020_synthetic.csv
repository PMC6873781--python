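class,Fp1,Fp2,F7,F3,Fz,F4,F8,T7,C3,Cz,C4,T8,P7,P3,Pz,P4,P8,O1,O2
A,0.1189,0.2897,-0.1101,0.0220,0.2003,0.3251,0.3355,-0.3021,-0.1669,0.0547,0.2286,0.2492,-0.3884,-0.2946,-0.1386,0.0086,0.0573,-0.3300,-0.1591
B,0.2897,0.1189,0.3355,0.3251,0.2003,0.0220,-0.1101,0.2492,0.2286,0.0547,-0.1669,-0.3021,0.0573,0.0086,-0.1386,-0.2946,-0.3884,-0.1591,-0.3300
C,0.3084,0.3084,0.1724,0.2571,0.2948,0.2571,0.1724,-0.0356,0.0415,0.0736,0.0415,-0.0356,-0.2435,-0.2160,-0.2119,-0.2160,-0.2435,-0.3626,-0.3626
D,-0.0544,-0.0544,-0.1374,0.1993,0.3983,0.1993,-0.1374,-0.1974,0.2204,0.5344,0.2204,-0.1974,-0.2475,-0.0368,0.0778,-0.0368,-0.2475,-0.2514,-0.2514
E,-0.2849,-0.2849,-0.2512,-0.1900,-0.1647,-0.1900,-0.2512,-0.1478,0.0514,0.1761,0.0514,-0.1478,0.0307,0.3110,0.4714,0.3110,0.0307,0.2393,0.2393
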