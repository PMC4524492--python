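symbol	category
accD	protein
atpA	protein
atpB	protein
atpE	protein
atpF	protein
atpH	protein
atpI	protein
cemA	protein
clpP	protein
ftsH	protein
petA	protein
petB	protein
petD	protein
petG	protein
psaA	protein
psaB	protein
psaC	protein
psaI	protein
psaJ	protein
psaM	protein
psbA	protein
psbB	protein
psbC	protein
psbD	protein
psbE	protein
psbF	protein
psbH	protein
psbI	protein
psbJ	protein
psbK	protein
psbL	protein
psbM	protein
psbN	protein
psbT	protein
psbZ	protein
rbcL	protein
rpl2	protein
rpl5	protein
rpl12	protein
rpl14	protein
rpl16	protein
rpl19	protein
rpl20	protein
rpl23	protein
rpl36	protein
rpoA	protein
rpoB	protein
rpoC1	protein
rpoC2	protein
rps2	protein
rps3	protein
rps7	protein
rps8	protein
rps9	protein
rps11	protein
rps12	protein
rps18	protein
rps19	protein
tufA	protein
ycf1	protein
ycf3	protein
ycf4	protein
ycf20	protein
rrf	rRNA
rrl	rRNA
rrs	rRNA
trnA(ugc)	tRNA
trnC(gca)	tRNA
trnD(guc)	tRNA
trnE(uuc)	tRNA
trnF(gaa)	tRNA
trnG(gcc)	tRNA
trnG(ucc)	tRNA
trnH(gug)	tRNA
trnI(gau)	tRNA
trnK(uuu)	tRNA
trnL(uaa)	tRNA
trnL(uag)	tRNA
trnMe(cau)	tRNA
trnMf(cau)	tRNA
trnN(guu)	tRNA
trnP(ugg)	tRNA
trnQ(uug)	tRNA
trnR(ucu)	tRNA
trnR(acg)	tRNA
trnS(gcu)	tRNA
trnS(uga)	tRNA
trnT(ugu)	tRNA
trnV(uac)	tRNA
trnW(cca)	tRNA
trnY(gua)	tRNA
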