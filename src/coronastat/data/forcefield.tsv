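# minimal nonbonded parameter table (OPLS-like): geometric combination
# type	sigma_nm	epsilon_kJmol	charge_e
C_pro	0.350	0.276	0.0
N_pro	0.325	0.711	0.0
O_pro	0.296	0.879	0.0
S_pro	0.355	1.046	0.0
P_pro	0.374	0.837	0.0
H_pro	0.242	0.126	0.0
O_carboxylate	0.296	0.879	-0.5
N_lysine	0.325	0.711	1.0
N_arginine	0.325	0.711	0.5
C_gra	0.355	0.293	0.0
C_ipso	0.355	0.293	0.185
O_oh	0.312	0.711	-0.585
H_oh	0.010	0.000	0.400
AU	0.293	0.229	0.0
S_thiol	0.355	1.046	0.0
C_thiol	0.350	0.276	0.0
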