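# Instrument MRM parameters per transition: published exact mass and
# precursor m/z, product ion m/z, retention-time window (min), collision
# energy (V) and cell accelerator voltage (V). The retention times and
# voltages are measured quantities; the mass columns are kept only to
# cross-check the computed values (the table builder recomputes masses from
# elemental composition and warns where a published entry disagrees).
compound,exact_mass_printed,precursor_printed,product_mz,rt_min_lo,rt_min_hi,collision_energy_V,cell_accelerator_V
d(A*A),581.14388,581.1,136.1,12.4,12.5,40,3
d(A*C),557.13264,557.1,136.1,10.9,11.0,32,3
d(A*C),557.13264,557.1,112.1,10.9,11.0,24,3
d(A*G),597.13879,597.1,152.1,9.61,9.70,48,5
d(A*G),597.13879,597.1,136.1,9.70,9.70,36,1
d(A*T),573.13231,572.1,136.1,14.8,14.8,32,1
d(A*T),573.13231,572.1,127.1,14.8,14.8,48,5
d(C*A),557.13264,557.1,136.1,8.27,8.29,32,1
d(C*A),557.13264,557.1,112.1,8.27,8.29,28,3
d(C*C),533.12141,533.1,112.1,5.31,5.47,16,5
d(C*G),573.12756,573.1,152.1,5.11,5.31,32,1
d(C*G),573.12756,573.1,112.1,5.11,5.31,32,5
d(C*T),548.12108,548.1,127.1,8.79,8.81,36,5
d(C*T),548.12108,548.1,112.1,8.79,8.81,28,5
d(G*A),597.13879,597.1,152.1,9.61,9.70,28,3
d(G*A),597.13879,597.1,136.1,9.61,9.70,32,1
d(G*C),573.12756,573.1,152.1,7.64,7.65,32,5
d(G*C),573.12756,573.1,112.1,7.64,7.65,40,3
d(G*G),613.13371,613.1,152.1,7.14,7.20,36,3
d(G*T),588.12722,588.1,152.1,11.5,11.6,32,5
d(G*T),588.12722,588.1,127.1,11.5,11.6,40,3
d(T*A),573.13231,572.1,136.1,12.92,12.92,28,3
d(T*A),573.13231,572.1,127.1,12.9,12.9,44,3
d(T*C),548.12108,548.1,127.1,10.1,10.2,44,1
d(T*C),548.12108,548.1,112.1,10.1,10.2,24,5
d(T*G),588.12722,588.1,152.1,9.18,9.20,32,5
d(T*G),588.12722,588.1,127.1,9.18,9.20,48,1
d(T*T),563.12074,563.1,127.1,14.4,14.4,40,5
dA,252.10912,252.1,136.1,5.23,5.23,12,1
dC,228.09788,228.1,112.1,1.45,1.45,16,1
dG,268.10403,268.1,152.1,2.7,2.7,14,3
dT,243.09755,243.1,127.1,3.22,3.22,12,1
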