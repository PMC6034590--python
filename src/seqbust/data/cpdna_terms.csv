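Locus,Type,Name,IntronExonNumber
matK,CDS,matK,
matK,CDS,matk,
matK,CDS,maturase K,
matK,CDS,maturase,
rbcL,CDS,rbcL,
rbcL,CDS,rbcl,
rbcL,CDS,ribulose-1 5-bisphosphate carboxylase/oxygenase large subunit,
rbcL,CDS,ribulose 1 5-bisphosphate carboxylase/oxygenase large subunit,
rbcL,CDS,ribulose bisphosphate carboxylase large chain,
rbcL,CDS,RuBisCO large subunit,
ndhF,CDS,ndhF,
ndhF,CDS,NADH dehydrogenase subunit F,
ndhF,CDS,NADH-plastoquinone oxidoreductase subunit 5,
atpB,CDS,atpB,
atpB,CDS,ATP synthase CF1 beta subunit,
atpB,CDS,ATPase beta subunit,
psbA,CDS,psbA,
psbA,CDS,photosystem II protein D1,
psbA,CDS,PSII 32 kDa protein,
rpoB,CDS,rpoB,
rpoB,CDS,RNA polymerase beta subunit,
rpoC1,CDS,rpoC1,
rpoC1,CDS,RNA polymerase beta' subunit,
rpoC2,CDS,rpoC2,
rpoC2,CDS,RNA polymerase beta'' subunit,
accD,CDS,accD,
accD,CDS,acetyl-CoA carboxylase beta subunit,
ccsA,CDS,ccsA,
ccsA,CDS,cytochrome c biogenesis protein,
cemA,CDS,cemA,
cemA,CDS,envelope membrane protein,
clpP,CDS,clpP,
clpP,CDS,clp protease proteolytic subunit,
petA,CDS,petA,
petA,CDS,cytochrome f,
psaA,CDS,psaA,
psaA,CDS,photosystem I P700 chlorophyll a apoprotein A1,
psaB,CDS,psaB,
psaB,CDS,photosystem I P700 chlorophyll a apoprotein A2,
psbB,CDS,psbB,
psbB,CDS,photosystem II CP47 chlorophyll apoprotein,
ycf1,CDS,ycf1,
ycf1,CDS,hypothetical chloroplast RF1,
ycf2,CDS,ycf2,
ycf2,CDS,hypothetical chloroplast RF2,
rps16,CDS,rps16,
rps16,CDS,ribosomal protein S16,
rrn16,rRNA,16S ribosomal RNA,
rrn16,rRNA,rrn16,
rrn23,rRNA,23S ribosomal RNA,
rrn23,rRNA,rrn23,
trnL,tRNA,trnL-UAA,
trnL,tRNA,tRNA-Leu,
trnL,tRNA,trnL,
trnH,tRNA,trnH-GUG,
trnH,tRNA,tRNA-His,
trnH,tRNA,trnH,
trnK,tRNA,trnK-UUU,
trnK,tRNA,tRNA-Lys,
trnK,tRNA,trnK,
trnL_intron,intron,trnL,1
trnL_intron,intron,tRNA-Leu,1
trnK_intron,intron,trnK,1
trnK_intron,intron,tRNA-Lys,1
rps16_intron,intron,rps16,1
trnL_exon1,exon,trnL,1
trnL_exon2,exon,trnL,2
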