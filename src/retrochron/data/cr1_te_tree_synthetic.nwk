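(CR1_Xenopus_amph,(((CR1_A_aves,CR1_A_croc),CR1_A_turt)GroupA,(((CR1_B_mono,CR1_B_ther),CR1_B_turt)GroupB,((CR1_D_croc,CR1_D_turt)GroupD,((CR1_C_ther,(CR1_C_lepi,(CR1_C_croc,CR1_C_turt)))GroupC,((CR1_E_croc1,CR1_E_croc2)GroupE,(((CR1_F_croc,CR1_F_turt),CR1_F_aves)GroupF,((CR1_G_mono,CR1_G_ther),(CR1_G_croc,CR1_G_turt))GroupG)Backbone6)Backbone5)Backbone4)Backbone3)Backbone2)Backbone1)CR1Root;
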