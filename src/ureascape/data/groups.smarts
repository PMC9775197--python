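# Functional-family census catalog: name<TAB>SMARTS, one per line.
# Editable data, not code; names follow common medicinal-chemistry usage.
urea	[NX3][CX3](=O)[NX3]
thiourea	[NX3][CX3](=S)[NX3]
hydroxamic_acid	[CX3](=O)[NX3][OX2H1,OX1-]
hydrazine	[NX3][NX3]
hydrazide	[CX3](=O)[NX3][NX3]
sulfonamide	[SX4](=O)(=O)[NX3]
nitro	[NX3+](=O)[O-]
catechol	c1cc(O)c(O)cc1
thiol	[SX2H]
barbiturate	O=C1NC(=O)NC(=O)C1
coumarin	O=c1ccc2ccccc2o1
phosphoramide	[PX4](=O)([NX3])[NX3]
aliphatic_long_chain	[CH2][CH2][CH2][CH2][CH2][CH2][CH2]
aryl_hydroxyl	c[OX2H]
imine	[CX3]=[NX2]
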