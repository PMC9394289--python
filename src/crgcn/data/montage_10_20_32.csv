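name,x,y,z
Fp1,-0.30133,0.85901,-0.07155
AF3,-0.34498,0.78654,0.21729
F3,-0.51432,0.54367,0.43190
F7,-0.71924,0.43479,-0.11690
FC5,-0.79041,0.19084,0.25038
FC1,-0.34867,0.26626,0.81878
C3,-0.66904,-0.11907,0.65880
T7,-0.86151,-0.16397,-0.09567
CP5,-0.81474,-0.47651,0.31681
CP1,-0.36353,-0.48410,0.93474
P3,-0.54261,-0.80651,0.57263
P7,-0.74147,-0.75190,-0.02546
PO3,-0.37375,-1.03238,0.38046
O1,-0.30109,-1.15108,0.09048
Oz,0.00110,-1.17609,0.15004
Pz,0.00332,-0.83033,0.84569
Fp2,0.30579,0.86903,-0.07247
AF4,0.36557,0.79564,0.22475
Fz,0.00320,0.59896,0.68034
F4,0.53062,0.55589,0.41779
F8,0.74770,0.45472,-0.12284
FC6,0.81415,0.20407,0.25016
FC2,0.35607,0.27063,0.80671
Cz,0.00410,-0.09384,1.02614
C4,0.68705,-0.11158,0.65083
T8,0.87092,-0.15375,-0.09714
CP6,0.85292,-0.47191,0.31944
CP2,0.39291,-0.48186,0.92840
P4,0.56983,-0.80418,0.57898
P8,0.74783,-0.74796,-0.02600
PO4,0.37651,-1.03234,0.37258
O2,0.30548,-1.14808,0.09008
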