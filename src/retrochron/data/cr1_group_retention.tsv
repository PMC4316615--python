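# extant landscape-detectable presence of CR1 groups A-G across amniote
# classes; low-copy avian relics of group F are below detection and are
# deliberately not listed here
# group	taxa (comma separated host-tree leaves)
A	Crocodylia,Testudines,Aves
B	Testudines,Monotremata,Theria
C	Crocodylia,Testudines,Lepidosauria,Theria
D	Crocodylia,Testudines
E	Crocodylia
F	Crocodylia,Testudines
G	Crocodylia,Testudines,Monotremata,Theria
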