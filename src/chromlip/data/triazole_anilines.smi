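# 1-substituted 4-[(aminophenoxy)methyl]-1H-1,2,3-triazoles.
# Series 2-6 vary the N1 substituent (allyl, benzyl, 4-nitrobenzyl,
# phenylthiomethyl, 4-chlorophenyl); a/b/c place the amino group
# ortho/meta/para on the aryloxy ring.
2a	C=CCn1cc(COc2ccccc2N)nn1
2b	C=CCn1cc(COc2cccc(N)c2)nn1
2c	C=CCn1cc(COc2ccc(N)cc2)nn1
3a	c1ccc(Cn2cc(COc3ccccc3N)nn2)cc1
3b	c1ccc(Cn2cc(COc3cccc(N)c3)nn2)cc1
3c	c1ccc(Cn2cc(COc3ccc(N)cc3)nn2)cc1
4a	O=[N+]([O-])c1ccc(Cn2cc(COc3ccccc3N)nn2)cc1
4b	O=[N+]([O-])c1ccc(Cn2cc(COc3cccc(N)c3)nn2)cc1
4c	O=[N+]([O-])c1ccc(Cn2cc(COc3ccc(N)cc3)nn2)cc1
5a	c1ccc(SCn2cc(COc3ccccc3N)nn2)cc1
5b	c1ccc(SCn2cc(COc3cccc(N)c3)nn2)cc1
5c	c1ccc(SCn2cc(COc3ccc(N)cc3)nn2)cc1
6a	Clc1ccc(-n2cc(COc3ccccc3N)nn2)cc1
6b	Clc1ccc(-n2cc(COc3cccc(N)c3)nn2)cc1
6c	Clc1ccc(-n2cc(COc3ccc(N)cc3)nn2)cc1
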