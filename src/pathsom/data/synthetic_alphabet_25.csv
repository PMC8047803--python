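letter,d0,d1,d2
A,0.5134485577879019,0.8168871710399762,0.5134485577879018
B,0.5134485577879019,0.751296330387238,0.5134485577879018
C,0.5134485577879019,0.6103695723661133,0.5134485577879018
D,0.5134485577879019,0.4322738101561354,0.5134485577879018
E,0.5134485577879019,0.31549482910064786,0.5134485577879019
F,0.5927122071505901,0.9180596594738573,0.5927122071505903
G,0.5927122071505901,0.8625793640648634,0.5927122071505903
H,0.5927122071505901,0.7481560873027711,0.5927122071505903
I,0.5927122071505901,0.6175688574972754,0.5927122071505901
J,0.5927122071505901,0.5454551501123891,0.5927122071505901
K,0.6581793068761734,1.0037476571840376,0.6581793068761734
L,0.6581793068761734,0.9642484244607648,0.6581793068761733
M,0.6581793068761734,0.8858623147513773,0.6581793068761733
N,0.6581793068761734,0.8027566705531388,0.6581793068761734
O,0.6581793068761734,0.7605420622117676,0.6581793068761734
P,0.7083259806549268,1.070443285792961,0.7083259806549269
Q,0.7083259806549268,1.048113829901189,0.7083259806549269
R,0.7083259806549268,1.0051303408343397,0.7083259806549268
S,0.7083259806549268,0.9617094600597474,0.7083259806549269
T,0.7083259806549268,0.9405974500376841,0.7083259806549268
U,0.7419849654111493,1.1156611221033375,0.7419849654111492
V,0.7419849654111493,1.1073337170468884,0.7419849654111492
W,0.7419849654111493,1.0916281219109771,0.7419849654111494
X,0.7419849654111493,1.0762121766964268,0.7419849654111494
Y,0.7419849654111493,1.0688857387639108,0.7419849654111494
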