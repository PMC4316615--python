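# synthetic class-level rendering of the amniote CR1 subfamily tree:
# te_leaf	host_node	group
CR1_Xenopus_amph	Amphibia	outgroup
CR1_A_aves	Aves	A
CR1_A_croc	Crocodylia	A
CR1_A_turt	Testudines	A
CR1_B_mono	Monotremata	B
CR1_B_ther	Theria	B
CR1_B_turt	Testudines	B
CR1_C_ther	Theria	C
CR1_C_lepi	Lepidosauria	C
CR1_C_croc	Crocodylia	C
CR1_C_turt	Testudines	C
CR1_D_croc	Crocodylia	D
CR1_D_turt	Testudines	D
CR1_E_croc1	Crocodylia	E
CR1_E_croc2	Crocodylia	E
CR1_F_croc	Crocodylia	F
CR1_F_turt	Testudines	F
CR1_F_aves	Aves	F
CR1_G_mono	Monotremata	G
CR1_G_ther	Theria	G
CR1_G_croc	Crocodylia	G
CR1_G_turt	Testudines	G
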