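analyte,is_group,bovine,caprine,ovine,loc25,loc75
ILE,0,33.2,45.7,49.1,37.4,47.9
LEU,0,30.2,40.9,51.5,35.5,46.3
VAL,0,28.4,40.5,44.4,32.3,43.2
BCAA,1,29.5,41.1,46.2,35.1,42.8
HIS,0,16.2,29.8,49.1,25.3,38.0
LYS,0,-20.1,1.4,33.4,-4.0,13.9
MET,0,9.3,14.7,40.3,14.7,28.2
PHE,0,24.2,36.9,45.5,29.6,41.5
THR,0,24.5,36.7,48.1,30.3,42.6
EAA,1,20.3,33.4,42.8,27.8,36.5
ALA,0,28.2,47.3,55.6,38.3,49.1
ARG,0,9.9,25.6,41.7,18.1,33.4
ASX,0,19.5,37.9,51.6,30.6,42.1
GLX,0,24.7,36.5,47.7,30.9,41.7
SER,0,20.5,33.8,46.2,27.2,39.8
TYR,0,16.3,33.8,17.4,15.4,29.5
NEAA,1,20.6,37.9,48.0,28.9,37.3
LNAA,1,19.2,37.4,32.7,23.6,32.6
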