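node_u,node_v,distance_km,occupancy,density,weight
A,B,96,1,6,6
F,J,76,1,6,6
F,G,15,1,5,5
L,M,76,1,5,5
F,E,30,7,34,4.9
K,M,61,1,4,4
D,H,75,2,7,3.5
B,C,16,1,2,2
B,H,111,1,2,2
H,J,44,1,2,2
F,H,33,6,11,1.8
E,H,61,3,5,1.7
B,K,197,1,1,1
F,I,32,1,1,1
H,G,38,1,1,1
I,G,26,1,1,1
L,K,71,1,1,1
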