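amino_acid,hydrophilicity,flexibility,accessibility,turn_propensity,exposed_surface,polarizability,antigenic_propensity,hydrophobicity_kd,hydrophobicity_es,net_charge_index,polarity_grantham,polarity_zimmerman,sasa,side_chain_volume
A,-0.5,0.357,0.3,0.66,0.48,0.046,1.15,1.8,0.62,0.007187,8.1,0.0,129.0,88.6
C,-1.0,0.346,0.9,1.19,0.32,0.128,-1.20,2.5,0.29,-0.036610,5.5,1.48,167.0,108.5
D,3.0,0.511,-0.6,1.46,0.81,0.105,0.65,-3.5,-0.90,-0.023820,13.0,49.70,193.0,111.1
E,3.0,0.497,-0.7,0.74,0.93,0.151,-0.71,-3.5,-0.74,0.006802,12.3,49.90,223.0,138.4
F,-2.5,0.314,0.5,0.60,0.42,0.290,-1.41,2.8,1.19,0.037552,5.2,0.35,240.0,189.9
G,0.0,0.544,0.3,1.56,0.51,0.000,-1.84,-0.4,0.48,0.179052,9.0,0.0,104.0,60.1
H,-0.5,0.323,-0.1,0.95,0.66,0.230,3.12,-3.2,-0.40,-0.010690,10.4,51.60,224.0,153.2
I,-1.8,0.462,0.7,0.47,0.39,0.186,-2.92,4.5,1.38,0.021631,5.2,0.13,197.0,166.7
K,3.0,0.466,-1.8,1.01,0.93,0.219,2.06,-3.9,-1.50,0.017708,11.3,49.50,236.0,168.6
L,-1.8,0.365,0.5,0.59,0.41,0.186,0.75,3.8,1.06,0.051672,4.9,0.13,201.0,166.7
M,-1.3,0.295,0.4,0.60,0.44,0.221,-3.85,1.9,0.64,0.002683,5.7,1.43,224.0,162.9
N,0.2,0.463,-0.5,1.56,0.82,0.134,-0.77,-3.5,-0.78,0.005392,11.6,3.38,195.0,114.1
P,0.0,0.509,-0.3,1.52,0.78,0.131,-0.53,-1.6,0.12,0.239531,8.0,1.58,159.0,112.7
Q,0.2,0.493,-0.7,0.98,0.81,0.180,-0.11,-3.5,-0.85,0.049211,10.5,3.53,225.0,143.8
R,3.0,0.529,-1.4,0.95,0.84,0.291,0.58,-4.5,-2.53,0.043587,10.5,52.00,274.0,173.4
S,0.3,0.507,-0.1,1.43,0.70,0.062,-0.26,-0.8,-0.18,0.004627,9.2,1.67,155.0,89.0
T,-0.4,0.444,-0.2,0.96,0.71,0.108,-0.45,-0.7,-0.05,0.003352,8.6,1.66,172.0,116.1
V,-1.5,0.386,0.6,0.50,0.40,0.140,-0.13,4.2,1.08,0.057004,5.9,0.13,174.0,140.0
W,-3.4,0.305,0.3,0.96,0.49,0.409,-1.14,-0.9,0.81,0.037977,5.4,2.10,285.0,227.8
Y,-2.3,0.420,-0.4,1.14,0.67,0.298,0.13,-1.3,0.26,0.023599,6.2,1.61,263.0,193.6
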