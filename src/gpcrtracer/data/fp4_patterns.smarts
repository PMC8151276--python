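# Functional-group substructure patterns for the 512-position FP4-style block.
# One pattern per line: <name><TAB><SMARTS>. Pattern i (0-based, in file
# order) sets position i of the block; positions beyond the last pattern are
# always zero. The list is vendored to freeze the dialect.
primary_carbon	[CX4H3][#6]
secondary_carbon	[CX4H2]([#6])[#6]
tertiary_carbon	[CX4H1]([#6])([#6])[#6]
quaternary_carbon	[CX4]([#6])([#6])([#6])[#6]
alkene	[CX3]=[CX3]
alkyne	[CX2]#[CX2]
allene	[CX3]=[CX2]=[CX3]
arene	c1ccccc1
heteroarene_n	[nX2,nX3]
heteroarene_o	[oX2]
heteroarene_s	[sX2]
alcohol	[OX2H][CX4]
primary_alcohol	[OX2H][CX4H2]
secondary_alcohol	[OX2H][CX4H1]
tertiary_alcohol	[OX2H][CX4D4]
phenol	[OX2H][c]
enol	[OX2H][CX3]=[CX3]
ether	[OD2]([#6])[#6]
dialkyl_ether	[OD2]([CX4])[CX4]
alkyl_aryl_ether	[OD2]([CX4])[c]
diaryl_ether	[OD2]([c])[c]
epoxide	C1OC1
peroxide	[OX2][OX2]
aldehyde	[CX3H1](=O)[#6]
ketone	[CX3](=O)([#6])[#6]
ketene	[CX3]=[CX2]=[OX1]
acetal	[CX4]([OX2])([OX2])[#6,#1]
hemiacetal	[CX4]([OX2H])([OX2])[#6,#1]
carboxylic_acid	[CX3](=O)[OX2H1]
carboxylate	[CX3](=O)[OX1-]
ester	[CX3](=O)[OX2][#6]
lactone	[CX3]1(=O)[OX2][#6][#6]1
carbonate	[OX2][CX3](=O)[OX2]
anhydride	[CX3](=O)[OX2][CX3](=O)
acyl_halide	[CX3](=O)[F,Cl,Br,I]
amide	[CX3](=O)[NX3]
primary_amide	[CX3](=O)[NX3H2]
secondary_amide	[CX3](=O)[NX3H1][#6]
tertiary_amide	[CX3](=O)[NX3]([#6])[#6]
lactam	[CX3]1(=O)[NX3][#6][#6]1
imide	[NX3]([CX3]=O)[CX3]=O
carbamate	[NX3][CX3](=O)[OX2]
urea	[NX3][CX3](=O)[NX3]
thiourea	[NX3][CX3](=S)[NX3]
guanidine	[NX3][CX3](=[NX2])[NX3]
amidine	[CX3](=[NX2])[NX3]
primary_amine	[NX3H2;!$(NC=O)][#6]
secondary_amine	[NX3H1;!$(NC=O)]([#6])[#6]
tertiary_amine	[NX3H0;!$(NC=O);!$(N=O)]([#6])([#6])[#6]
aryl_amine	[NX3][c]
quaternary_ammonium	[NX4+]
hydroxylamine	[NX3][OX2H]
hydrazine	[NX3][NX3]
hydrazone	[NX3][NX2]=[CX3]
imine	[CX3]=[NX2][#6,#1]
oxime	[CX3]=[NX2][OX2H]
nitrile	[NX1]#[CX2]
isocyanide	[NX2+]#[CX1-]
cyanamide	[NX3][CX2]#[NX1]
nitro	[NX3+](=O)[O-]
nitroso	[NX2]=[OX1]
nitrate	[OX2][NX3+](=O)[O-]
azide	[NX2]=[NX2+]=[NX1-]
azo	[NX2]=[NX2]
diazonium	[NX2+]#[NX1]
isocyanate	[NX2]=[CX2]=[OX1]
isothiocyanate	[NX2]=[CX2]=[SX1]
thiol	[SX2H]
thioether	[SX2]([#6])[#6]
disulfide	[SX2][SX2]
thioketone	[CX3](=[SX1])([#6])[#6]
thioamide	[CX3](=[SX1])[NX3]
thioester	[CX3](=O)[SX2][#6]
sulfoxide	[SX3](=[OX1])([#6])[#6]
sulfone	[SX4](=[OX1])(=[OX1])([#6])[#6]
sulfonic_acid	[SX4](=[OX1])(=[OX1])[OX2H]
sulfonate_ester	[SX4](=[OX1])(=[OX1])[OX2][#6]
sulfonamide	[SX4](=[OX1])(=[OX1])[NX3]
sulfamate	[NX3][SX4](=[OX1])(=[OX1])[OX2]
phosphine	[PX3]
phosphine_oxide	[PX4](=[OX1])
phosphate	[PX4](=[OX1])([OX2])([OX2])[OX2]
phosphonate	[PX4](=[OX1])([OX2])([OX2])[#6]
fluoro	[#6][F]
chloro	[#6][Cl]
bromo	[#6][Br]
iodo	[#6][I]
aryl_fluoride	[c][F]
aryl_chloride	[c][Cl]
aryl_bromide	[c][Br]
aryl_iodide	[c][I]
trifluoromethyl	[CX4]([F])([F])[F]
perfluoro_alkyl	[CX4]([F])([F])([F])[CX4]([F])[F]
gem_dihalide	[CX4]([F,Cl,Br,I])[F,Cl,Br,I]
vinyl_halide	[CX3]=[CX3][F,Cl,Br,I]
pyridine	c1ccncc1
pyridazine	c1ccnnc1
pyrimidine	c1cncnc1
pyrazine	c1cnccn1
triazine	c1ncncn1
pyrrole	c1cc[nH]c1
furan	c1ccoc1
thiophene	c1ccsc1
imidazole	c1c[nH]cn1
pyrazole	c1cc[nH]n1
oxazole	c1cnco1
isoxazole	c1cnoc1
thiazole	c1cncs1
isothiazole	c1cnsc1
triazole	c1nc[nH]n1
tetrazole	c1nn[nH]n1
indole	c1ccc2[nH]ccc2c1
benzimidazole	c1ccc2[nH]cnc2c1
benzofuran	c1ccc2occc2c1
benzothiophene	c1ccc2sccc2c1
quinoline	c1ccc2ncccc2c1
isoquinoline	c1ccc2cnccc2c1
quinazoline	c1ccc2ncncc2c1
purine	c1ncc2[nH]cnc2n1
naphthalene	c1ccc2ccccc2c1
biphenyl	c1ccc(-c2ccccc2)cc1
piperidine	C1CCNCC1
piperazine	C1CNCCN1
morpholine	C1COCCN1
thiomorpholine	C1CSCCN1
pyrrolidine	C1CCNC1
azetidine	C1CNC1
aziridine	C1CN1
tetrahydrofuran	C1CCOC1
tetrahydropyran	C1CCOCC1
dioxolane	C1OCCO1
cyclopropane	C1CC1
cyclobutane	C1CCC1
cyclopentane	C1CCCC1
cyclohexane	C1CCCCC1
spiro_carbon	[CX4](@[#6])(@[#6])(@[#6])@[#6]
ring_fusion_atom	[R2]
three_ring_atom	[R3]
macrocycle_atom	[r;!r3;!r4;!r5;!r6;!r7]
halogen_count	[F,Cl,Br,I]
oxygen_any	[#8]
nitrogen_any	[#7]
sulfur_any	[#16]
phosphorus_any	[#15]
boron_any	[#5]
silicon_any	[#14]
metal_any	[Li,Na,K,Mg,Ca,Fe,Zn,Cu,Mn,Co,Ni]
positive_charge	[+,+2,+3]
negative_charge	[-,-2,-3]
zwitterion_n	[NX4+,NX3+]
conjugated_dienone	[CX3]=[CX3][CX3]=[OX1]
michael_acceptor	[CX3]=[CX3][CX3](=[OX1])[#6,#7,#8]
alpha_halo_ketone	[CX3](=O)[CX4][F,Cl,Br,I]
benzylic_carbon	[CX4][c]
allylic_carbon	[CX4][CX3]=[CX3]
propargylic_carbon	[CX4][CX2]#[CX2]
vicinal_diol	[OX2H][CX4][CX4][OX2H]
amino_alcohol	[NX3][CX4][CX4][OX2H]
amino_acid_backbone	[NX3][CX4H]([#6])[CX3](=O)[OX2H1,OX1-]
peg_unit	[OX2][CX4H2][CX4H2][OX2]
n_methyl	[NX3][CX4H3]
o_methyl	[OX2][CX4H3]
s_methyl	[SX2][CX4H3]
dimethylamino	[NX3]([CX4H3])[CX4H3]
tert_butyl	[CX4]([CX4H3])([CX4H3])[CX4H3]
isopropyl	[CX4H1]([CX4H3])[CX4H3]
long_chain	[CX4H2][CX4H2][CX4H2][CX4H2][CX4H2]
aryl_methyl	[c][CX4H3]
diaryl_methane	[c][CX4H2][c]
aryl_carbonyl	[c][CX3]=[OX1]
aryl_nitrile	[c][CX2]#[NX1]
aryl_nitro	[c][NX3+](=O)[O-]
aryl_sulfonamide	[c][SX4](=[OX1])(=[OX1])[NX3]
aryl_hydroxyl_ortho_n	[OX2H]c1ccccn1
catechol	[OX2H]c1ccccc1[OX2H]
methylenedioxy	C1Oc2ccccc2O1
anisole	[CX4H3][OX2][c]
styrene	[c][CX3]=[CX3]
cinnamoyl	[c][CX3]=[CX3][CX3]=[OX1]
benzamide	[c][CX3](=O)[NX3]
anilide	[c][NX3][CX3]=[OX1]
benzyl_amine	[c][CX4H2][NX3]
phenethylamine	[c][CX4H2][CX4H2][NX3]
aryl_piperazine	[c][NX3]1[CX4H2][CX4H2][NX3][CX4H2][CX4H2]1
aryl_piperidine	[c][CX4,NX3]1[CX4H2][CX4H2][CX4H2,NX3][CX4H2][CX4H2]1
diazepine_ring	[#6]1[#6][#7][#6][#6][#7][#6]1
tricyclic_center	[R2]1[R1][R1][R1][R1][R2]1
xanthine_core	[#6]1(=O)[#7][#6](=O)[#7][#6]2[#7][#6][#7][#6]12
guanine_like	[NX3]c1ncc2ncnc2n1
adenine_like	[NX3H2]c1ncnc2[nH]cnc12
urea_cyclic	[NX3]1[CX3](=O)[NX3][#6][#6]1
hydantoin	[NX3]1[CX3](=O)[NX3][CX3]1=O
barbiturate	[NX3]1[CX3](=O)[NX3][CX3](=O)[CX4][CX3]1=O
coumarin_core	O=c1ccc2ccccc2o1
chromone_core	O=c1ccoc2ccccc12
flavone_core	O=c1cc(-c2ccccc2)oc2ccccc12
indanone	O=C1CCc2ccccc21
tetralin	C1CCc2ccccc2C1
steroid_ab_ring	C1CC2CCCC3CCCC(C1)C23
adamantyl	C1C2CC3CC1CC(C2)C3
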