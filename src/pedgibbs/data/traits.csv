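abbreviation,name
OH,Open hock
CH,Closed hock
Conv,Convergent
Diver,Divergent
CU,Camped under
CO,Camped out
PTF,Pigeon-toed forelimb
SFF,Splay-footed forelimb
BN,Base narrow
BW,Base wide
BUF,Broken and upright foot
CF,Coon foot
Straight,Club foot
Sloping,Sloping foot
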