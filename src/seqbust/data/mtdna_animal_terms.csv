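Locus,Type,Name,IntronExonNumber
ATP6,CDS,ATP6,
ATP6,CDS,atp6,
ATP6,CDS,ATPase6,
ATP6,CDS,ATPase 6,
ATP6,CDS,ATP synthase F0 subunit 6,
ATP6,CDS,ATP synthase subunit 6,
ATP6,CDS,ATPase subunit 6,
ATP8,CDS,ATP8,
ATP8,CDS,atp8,
ATP8,CDS,ATPase8,
ATP8,CDS,ATPase 8,
ATP8,CDS,ATP synthase F0 subunit 8,
ATP8,CDS,ATP synthase subunit 8,
ATP8,CDS,ATPase subunit 8,
COI,CDS,COI,
COI,CDS,CO1,
COI,CDS,COX1,
COI,CDS,cox1,
COI,CDS,COXI,
COI,CDS,cytochrome c oxidase subunit I,
COI,CDS,COX-I,
COI,CDS,cytochrome c oxidase subunit 1,
COI,CDS,cytochrome oxidase subunit I,
COI,CDS,cytochrome oxidase subunit 1,
COII,CDS,COII,
COII,CDS,CO2,
COII,CDS,COX2,
COII,CDS,cox2,
COII,CDS,COXII,
COII,CDS,cytochrome c oxidase subunit II,
COII,CDS,COX-II,
COII,CDS,cytochrome c oxidase subunit 2,
COII,CDS,cytochrome oxidase subunit II,
COII,CDS,cytochrome oxidase subunit 2,
COIII,CDS,COIII,
COIII,CDS,CO3,
COIII,CDS,COX3,
COIII,CDS,cox3,
COIII,CDS,COXIII,
COIII,CDS,cytochrome c oxidase subunit III,
COIII,CDS,COX-III,
COIII,CDS,cytochrome c oxidase subunit 3,
COIII,CDS,cytochrome oxidase subunit III,
COIII,CDS,cytochrome oxidase subunit 3,
CYTB,CDS,CYTB,
CYTB,CDS,cytb,
CYTB,CDS,cyt b,
CYTB,CDS,cob,
CYTB,CDS,cytochrome b,
CYTB,CDS,cytochrome b apoenzyme,
CYTB,CDS,Cyt-b,
ND1,CDS,ND1,
ND1,CDS,nad1,
ND1,CDS,NADH1,
ND1,CDS,NADH dehydrogenase subunit 1,
ND1,CDS,NADH dehydrogenase subunit I,
ND2,CDS,ND2,
ND2,CDS,nad2,
ND2,CDS,NADH2,
ND2,CDS,NADH dehydrogenase subunit 2,
ND2,CDS,NADH dehydrogenase subunit II,
ND3,CDS,ND3,
ND3,CDS,nad3,
ND3,CDS,NADH3,
ND3,CDS,NADH dehydrogenase subunit 3,
ND3,CDS,NADH dehydrogenase subunit III,
ND4,CDS,ND4,
ND4,CDS,nad4,
ND4,CDS,NADH4,
ND4,CDS,NADH dehydrogenase subunit 4,
ND4,CDS,NADH dehydrogenase subunit IV,
ND4L,CDS,ND4L,
ND4L,CDS,nad4L,
ND4L,CDS,NADH4L,
ND4L,CDS,NADH dehydrogenase subunit 4L,
ND4L,CDS,NADH dehydrogenase subunit IVL,
ND5,CDS,ND5,
ND5,CDS,nad5,
ND5,CDS,NADH5,
ND5,CDS,NADH dehydrogenase subunit 5,
ND5,CDS,NADH dehydrogenase subunit V,
ND6,CDS,ND6,
ND6,CDS,nad6,
ND6,CDS,NADH6,
ND6,CDS,NADH dehydrogenase subunit 6,
ND6,CDS,NADH dehydrogenase subunit VI,
tRNA_Ala,tRNA,tRNA-Ala,
tRNA_Ala,tRNA,trnA,
tRNA_Arg,tRNA,tRNA-Arg,
tRNA_Arg,tRNA,trnR,
tRNA_Asn,tRNA,tRNA-Asn,
tRNA_Asn,tRNA,trnN,
tRNA_Asp,tRNA,tRNA-Asp,
tRNA_Asp,tRNA,trnD,
tRNA_Cys,tRNA,tRNA-Cys,
tRNA_Cys,tRNA,trnC,
tRNA_Gln,tRNA,tRNA-Gln,
tRNA_Gln,tRNA,trnQ,
tRNA_Glu,tRNA,tRNA-Glu,
tRNA_Glu,tRNA,trnE,
tRNA_Gly,tRNA,tRNA-Gly,
tRNA_Gly,tRNA,trnG,
tRNA_His,tRNA,tRNA-His,
tRNA_His,tRNA,trnH,
tRNA_Ile,tRNA,tRNA-Ile,
tRNA_Ile,tRNA,trnI,
tRNA_LeuUUR,tRNA,tRNA-Leu,
tRNA_LeuUUR,tRNA,trnL,
tRNA_LeuUUR,tRNA,tRNA-Leu(UUR),
tRNA_LeuUUR,tRNA,trnL(UUR),
tRNA_LeuCUN,tRNA,tRNA-Leu(CUN),
tRNA_LeuCUN,tRNA,trnL(CUN),
tRNA_LeuCUN,tRNA,trnL2,
tRNA_Lys,tRNA,tRNA-Lys,
tRNA_Lys,tRNA,trnK,
tRNA_Met,tRNA,tRNA-Met,
tRNA_Met,tRNA,trnM,
tRNA_Phe,tRNA,tRNA-Phe,
tRNA_Phe,tRNA,trnF,
tRNA_Pro,tRNA,tRNA-Pro,
tRNA_Pro,tRNA,trnP,
tRNA_SerUCN,tRNA,tRNA-Ser,
tRNA_SerUCN,tRNA,trnS,
tRNA_SerUCN,tRNA,tRNA-Ser(UCN),
tRNA_SerUCN,tRNA,trnS(UCN),
tRNA_SerAGY,tRNA,tRNA-Ser(AGY),
tRNA_SerAGY,tRNA,trnS(AGY),
tRNA_SerAGY,tRNA,trnS2,
tRNA_Thr,tRNA,tRNA-Thr,
tRNA_Thr,tRNA,trnT,
tRNA_Trp,tRNA,tRNA-Trp,
tRNA_Trp,tRNA,trnW,
tRNA_Tyr,tRNA,tRNA-Tyr,
tRNA_Tyr,tRNA,trnY,
tRNA_Val,tRNA,tRNA-Val,
tRNA_Val,tRNA,trnV,
rRNA_12S,rRNA,12S ribosomal RNA,
rRNA_12S,rRNA,12S rRNA,
rRNA_12S,rRNA,s-rRNA,
rRNA_12S,rRNA,rrnS,
rRNA_12S,rRNA,small subunit ribosomal RNA,
rRNA_12S,rRNA,12S,
rRNA_16S,rRNA,16S ribosomal RNA,
rRNA_16S,rRNA,16S rRNA,
rRNA_16S,rRNA,l-rRNA,
rRNA_16S,rRNA,rrnL,
rRNA_16S,rRNA,large subunit ribosomal RNA,
rRNA_16S,rRNA,16S,
D-loop,D-loop,,
D-loop,D-loop,D-loop,
D-loop,D-loop,control region,
D-loop,misc_feature,control region,
D-loop,misc_feature,D-loop,
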