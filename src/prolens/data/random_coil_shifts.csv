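residue,nucleus,coil_shift,alpha_secondary,beta_secondary
A,CA,52.5,3.1,-1.5
A,CB,19.1,-0.5,2.2
A,HA,4.32,-0.38,0.38
R,CA,56.0,3.1,-1.5
R,CB,30.9,-0.5,2.2
R,HA,4.34,-0.38,0.38
N,CA,52.8,3.1,-1.5
N,CB,38.9,-0.5,2.2
N,HA,4.74,-0.38,0.38
D,CA,54.2,3.1,-1.5
D,CB,41.1,-0.5,2.2
D,HA,4.64,-0.38,0.38
C,CA,58.2,3.1,-1.5
C,CB,28.0,-0.5,2.2
C,HA,4.71,-0.38,0.38
Q,CA,56.6,3.1,-1.5
Q,CB,29.2,-0.5,2.2
Q,HA,4.34,-0.38,0.38
E,CA,56.6,3.1,-1.5
E,CB,29.9,-0.5,2.2
E,HA,4.35,-0.38,0.38
G,CA,45.1,3.1,-1.5
G,HA,3.96,-0.38,0.38
H,CA,55.0,3.1,-1.5
H,CB,29.0,-0.5,2.2
H,HA,4.6,-0.38,0.38
I,CA,61.1,3.1,-1.5
I,CB,38.8,-0.5,2.2
I,HA,4.17,-0.38,0.38
L,CA,55.1,3.1,-1.5
L,CB,42.4,-0.5,2.2
L,HA,4.34,-0.38,0.38
K,CA,56.2,3.1,-1.5
K,CB,33.1,-0.5,2.2
K,HA,4.32,-0.38,0.38
M,CA,55.4,3.1,-1.5
M,CB,32.9,-0.5,2.2
M,HA,4.48,-0.38,0.38
F,CA,57.7,3.1,-1.5
F,CB,39.6,-0.5,2.2
F,HA,4.62,-0.38,0.38
P,CA,63.3,3.1,-1.5
P,CB,32.1,-0.5,2.2
P,HA,4.42,-0.38,0.38
S,CA,58.3,3.1,-1.5
S,CB,63.8,-0.5,2.2
S,HA,4.47,-0.38,0.38
T,CA,61.8,3.1,-1.5
T,CB,69.8,-0.5,2.2
T,HA,4.35,-0.38,0.38
W,CA,57.5,3.1,-1.5
W,CB,29.6,-0.5,2.2
W,HA,4.66,-0.38,0.38
Y,CA,57.9,3.1,-1.5
Y,CB,38.8,-0.5,2.2
Y,HA,4.55,-0.38,0.38
V,CA,62.2,3.1,-1.5
V,CB,32.9,-0.5,2.2
V,HA,4.12,-0.38,0.38
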