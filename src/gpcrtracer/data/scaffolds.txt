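# Drug-like scaffold cores for the synthetic ligand generator.
# One record per line: <name><TAB><SMILES>. All entries parse with RDKit.
phenylpiperazine	C1CN(c2ccccc2)CCN1
indole	c1ccc2[nH]ccc2c1
quinoline	c1ccc2ncccc2c1
benzimidazole	c1ccc2[nH]cnc2c1
purine	c1ncc2[nH]cnc2n1
dibenzofuran	c1ccc2c(c1)oc1ccccc12
carbazole	c1ccc2c(c1)[nH]c1ccccc12
benzothiophene	c1ccc2sccc2c1
coumarin	O=c1ccc2ccccc2o1
naphthalene	c1ccc2ccccc2c1
tetrahydroisoquinoline	C1Cc2ccccc2CN1
benzodiazepinone	O=C1CN=C(c2ccccc2)c2ccccc2N1
phenothiazine	c1ccc2c(c1)Nc1ccccc1S2
xanthine	Cn1c(=O)c2[nH]cnc2n(C)c1=O
phenylmorpholine	C1COCCN1c1ccccc1
phenylisoxazole	c1ccc(-c2ccno2)cc1
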