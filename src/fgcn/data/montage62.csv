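name,x,y,grid_row,grid_col
FP1,-1.0,3.5,0,3
FPZ,0.0,3.5,0,4
FP2,1.0,3.5,0,5
AF3,-2.0,3.5,0,2
AF4,2.0,3.5,0,6
F7,-4.0,2.5,1,0
F5,-3.0,2.5,1,1
F3,-2.0,2.5,1,2
F1,-1.0,2.5,1,3
FZ,0.0,2.5,1,4
F2,1.0,2.5,1,5
F4,2.0,2.5,1,6
F6,3.0,2.5,1,7
F8,4.0,2.5,1,8
FT7,-4.0,1.5,2,0
FC5,-3.0,1.5,2,1
FC3,-2.0,1.5,2,2
FC1,-1.0,1.5,2,3
FCZ,0.0,1.5,2,4
FC2,1.0,1.5,2,5
FC4,2.0,1.5,2,6
FC6,3.0,1.5,2,7
FT8,4.0,1.5,2,8
T7,-4.0,0.5,3,0
C5,-3.0,0.5,3,1
C3,-2.0,0.5,3,2
C1,-1.0,0.5,3,3
CZ,0.0,0.5,3,4
C2,1.0,0.5,3,5
C4,2.0,0.5,3,6
C6,3.0,0.5,3,7
T8,4.0,0.5,3,8
TP7,-4.0,-0.5,4,0
CP5,-3.0,-0.5,4,1
CP3,-2.0,-0.5,4,2
CP1,-1.0,-0.5,4,3
CPZ,0.0,-0.5,4,4
CP2,1.0,-0.5,4,5
CP4,2.0,-0.5,4,6
CP6,3.0,-0.5,4,7
TP8,4.0,-0.5,4,8
P7,-4.0,-1.5,5,0
P5,-3.0,-1.5,5,1
P3,-2.0,-1.5,5,2
P1,-1.0,-1.5,5,3
PZ,0.0,-1.5,5,4
P2,1.0,-1.5,5,5
P4,2.0,-1.5,5,6
P6,3.0,-1.5,5,7
P8,4.0,-1.5,5,8
PO7,-3.0,-2.5,6,1
PO5,-2.0,-2.5,6,2
PO3,-1.0,-2.5,6,3
POZ,0.0,-2.5,6,4
PO4,1.0,-2.5,6,5
PO6,2.0,-2.5,6,6
PO8,3.0,-2.5,6,7
CB1,-2.0,-3.5,7,2
O1,-1.0,-3.5,7,3
OZ,0.0,-3.5,7,4
O2,1.0,-3.5,7,5
CB2,2.0,-3.5,7,6
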