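symbol	ancestral_side
rrs	rdna
trnI(gau)	rdna
trnA(ugc)	rdna
rrl	rdna
rrf	rdna
psaC	ssc_side
ycf1	ssc_side
ycf20	ssc_side
trnN(guu)	ssc_side
trnL(uag)	ssc_side
accD	lsc_side
atpA	lsc_side
atpB	lsc_side
atpE	lsc_side
atpF	lsc_side
atpH	lsc_side
atpI	lsc_side
cemA	lsc_side
clpP	lsc_side
ftsH	lsc_side
petA	lsc_side
petB	lsc_side
petD	lsc_side
petG	lsc_side
psaA	lsc_side
psaB	lsc_side
psaI	lsc_side
psaJ	lsc_side
psaM	lsc_side
psbA	lsc_side
psbB	lsc_side
psbC	lsc_side
psbD	lsc_side
psbE	lsc_side
psbF	lsc_side
psbH	lsc_side
psbI	lsc_side
psbJ	lsc_side
psbK	lsc_side
psbL	lsc_side
psbM	lsc_side
psbN	lsc_side
psbT	lsc_side
psbZ	lsc_side
rbcL	lsc_side
rpl2	lsc_side
rpl5	lsc_side
rpl12	lsc_side
rpl14	lsc_side
rpl16	lsc_side
rpl19	lsc_side
rpl20	lsc_side
rpl23	lsc_side
rpl36	lsc_side
rpoA	lsc_side
rpoB	lsc_side
rpoC1	lsc_side
rpoC2	lsc_side
rps2	lsc_side
rps3	lsc_side
rps7	lsc_side
rps8	lsc_side
rps9	lsc_side
rps11	lsc_side
rps12	lsc_side
rps18	lsc_side
rps19	lsc_side
tufA	lsc_side
ycf3	lsc_side
ycf4	lsc_side
trnC(gca)	lsc_side
trnD(guc)	lsc_side
trnE(uuc)	lsc_side
trnF(gaa)	lsc_side
trnG(gcc)	lsc_side
trnG(ucc)	lsc_side
trnH(gug)	lsc_side
trnK(uuu)	lsc_side
trnL(uaa)	lsc_side
trnMe(cau)	lsc_side
trnMf(cau)	lsc_side
trnP(ugg)	lsc_side
trnQ(uug)	lsc_side
trnR(ucu)	lsc_side
trnR(acg)	lsc_side
trnS(gcu)	lsc_side
trnS(uga)	lsc_side
trnT(ugu)	lsc_side
trnV(uac)	lsc_side
trnW(cca)	lsc_side
trnY(gua)	lsc_side
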