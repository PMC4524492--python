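raw	symbol
rrn16	rrs
rrn23	rrl
rrn5	rrf
16S	rrs
23S	rrl
5S	rrf
16S rRNA	rrs
23S rRNA	rrl
5S rRNA	rrf
rrn16S	rrs
rrn23S	rrl
rrn5S	rrf
rbcl	rbcL
trnM-CAU	trnMe(cau)
trnfM-CAU	trnMf(cau)
trnM(cau)	trnMe(cau)
trnfM(cau)	trnMf(cau)
ycf62	ycf20
infA	infA
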