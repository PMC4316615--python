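(Amphibia:350,((Monotremata:190,Theria:190)Mammalia:130,(Lepidosauria:280,(Testudines:260,(Crocodylia:240,Aves:240)Archosauria:20)Archelosauria:20)Sauropsida:40)Amniota:30)Tetrapoda;
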