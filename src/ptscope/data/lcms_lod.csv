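# Per-dinucleotide LC-MS limits of detection on the per-10^6-nt level scale.
# Baseline 1.0 reflects the lower bound of reliably quantified fecal-DNA
# levels; G*C is five-fold less sensitive than G*A on this instrument, so
# its LOD is raised accordingly.
dinucleotide,lod_level_per_1e6
A*A,1.0
A*C,1.0
A*G,1.0
A*T,1.0
C*A,1.0
C*C,1.0
C*G,1.0
C*T,1.0
G*A,1.0
G*C,5.0
G*G,1.0
G*T,1.0
T*A,1.0
T*C,1.0
T*G,1.0
T*T,1.0
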