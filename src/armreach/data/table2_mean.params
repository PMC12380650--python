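# Planar three-joint arm segment parameters, profile "table2_mean".
# Group-mean anthropometric estimates (upper arm, forearm, hand).
# Units: lengths m, masses kg, inertias kg*m^2.
#
# Convention: I_i is the moment of inertia of link i about its PROXIMAL
# joint axis (shoulder, elbow, wrist respectively), not about the link
# centre of mass.  The inertia-matrix assembly in arm_model relies on
# this: the own-link rotational term uses I_i directly and no extra
# parallel-axis term is added for the link's own mass.
L1 = 0.283
L2 = 0.240
L3 = 0.195
Lg1 = 0.110
Lg2 = 0.0928
Lg3 = 0.0674
m1 = 1.617
m2 = 0.878
m3 = 0.512
I1 = 0.0363
I2 = 0.0128
I3 = 0.00438
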