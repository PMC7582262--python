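amino_acid,helix_propensity,sheet_propensity,turn_propensity,pka_carboxyl,pka_amine,pka_side_chain,isoelectric_point,atoms_carbon,atoms_hydrogen,atoms_nitrogen,atoms_oxygen,atoms_sulfur,atoms_heavy,residue_mass,max_asa,hydropathy,volume,polarity,flexibility
A,1.42,0.83,0.66,2.34,9.69,0.0,6.00,3,7,1,2,0,6,71.08,129.0,1.8,88.6,8.1,0.357
C,0.70,1.19,1.19,1.96,10.28,8.18,5.07,3,7,1,2,1,7,103.14,167.0,2.5,108.5,5.5,0.346
D,1.01,0.54,1.46,1.88,9.60,3.65,2.77,4,7,1,4,0,9,115.09,193.0,-3.5,111.1,13.0,0.511
E,1.51,0.37,0.74,2.19,9.67,4.25,3.22,5,9,1,4,0,10,129.12,223.0,-3.5,138.4,12.3,0.497
F,1.13,1.38,0.60,1.83,9.13,0.0,5.48,9,11,1,2,0,12,147.18,240.0,2.8,189.9,5.2,0.314
G,0.57,0.75,1.56,2.34,9.60,0.0,5.97,2,5,1,2,0,5,57.05,104.0,-0.4,60.1,9.0,0.544
H,1.00,0.87,0.95,1.82,9.17,6.00,7.59,6,9,3,2,0,11,137.14,224.0,-3.2,153.2,10.4,0.323
I,1.08,1.60,0.47,2.36,9.60,0.0,6.02,6,13,1,2,0,9,113.16,197.0,4.5,166.7,5.2,0.462
K,1.16,0.74,1.01,2.18,8.95,10.53,9.74,6,14,2,2,0,10,128.17,236.0,-3.9,168.6,11.3,0.466
L,1.21,1.30,0.59,2.36,9.60,0.0,5.98,6,13,1,2,0,9,113.16,201.0,3.8,166.7,4.9,0.365
M,1.45,1.05,0.60,2.28,9.21,0.0,5.74,5,11,1,2,1,9,131.19,224.0,1.9,162.9,5.7,0.295
N,0.67,0.89,1.56,2.02,8.80,0.0,5.41,4,8,2,3,0,9,114.10,195.0,-3.5,114.1,11.6,0.463
P,0.57,0.55,1.52,1.99,10.60,0.0,6.30,5,9,1,2,0,8,97.12,159.0,-1.6,112.7,8.0,0.509
Q,1.11,1.10,0.98,2.17,9.13,0.0,5.65,5,10,2,3,0,10,128.13,225.0,-3.5,143.8,10.5,0.493
R,0.98,0.93,0.95,2.17,9.04,12.48,10.76,6,14,4,2,0,12,156.19,274.0,-4.5,173.4,10.5,0.529
S,0.77,0.75,1.43,2.21,9.15,0.0,5.68,3,7,1,3,0,7,87.08,155.0,-0.8,89.0,9.2,0.507
T,0.83,1.19,0.96,2.09,9.10,0.0,5.60,4,9,1,3,0,8,101.10,172.0,-0.7,116.1,8.6,0.444
V,1.06,1.70,0.50,2.32,9.62,0.0,5.96,5,11,1,2,0,8,99.13,174.0,4.2,140.0,5.9,0.386
W,1.08,1.37,0.96,2.83,9.39,0.0,5.89,11,12,2,2,0,15,186.21,285.0,-0.9,227.8,5.4,0.305
Y,0.69,1.47,1.14,2.20,9.11,10.07,5.66,9,11,1,3,0,13,163.18,263.0,-1.3,193.6,6.2,0.420
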