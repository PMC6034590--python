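Locus,Type,Name,IntronExonNumber
atp1,CDS,atp1,
atp1,CDS,ATPase subunit 1,
atp1,CDS,ATP synthase F1 subunit 1,
atp4,CDS,atp4,
atp4,CDS,ATPase subunit 4,
atp6,CDS,atp6,
atp6,CDS,ATPase subunit 6,
atp6,CDS,ATP synthase F0 subunit 6,
atp8,CDS,atp8,
atp8,CDS,ATPase subunit 8,
atp9,CDS,atp9,
atp9,CDS,ATPase subunit 9,
ccmB,CDS,ccmB,
ccmB,CDS,cytochrome c biogenesis B,
ccmC,CDS,ccmC,
ccmC,CDS,cytochrome c biogenesis C,
ccmFc,CDS,ccmFc,
ccmFc,CDS,cytochrome c biogenesis Fc,
ccmFn,CDS,ccmFn,
ccmFn,CDS,cytochrome c biogenesis Fn,
cob,CDS,cob,
cob,CDS,apocytochrome b,
cob,CDS,cytochrome b,
cox1,CDS,cox1,
cox1,CDS,COX1,
cox1,CDS,cytochrome c oxidase subunit 1,
cox2,CDS,cox2,
cox2,CDS,COX2,
cox2,CDS,cytochrome c oxidase subunit 2,
cox3,CDS,cox3,
cox3,CDS,COX3,
cox3,CDS,cytochrome c oxidase subunit 3,
matR,CDS,matR,
matR,CDS,maturase R,
mttB,CDS,mttB,
mttB,CDS,transport membrane protein,
nad1,CDS,nad1,
nad1,CDS,NADH dehydrogenase subunit 1,
nad2,CDS,nad2,
nad2,CDS,NADH dehydrogenase subunit 2,
nad3,CDS,nad3,
nad3,CDS,NADH dehydrogenase subunit 3,
nad4,CDS,nad4,
nad4,CDS,NADH dehydrogenase subunit 4,
nad4L,CDS,nad4L,
nad4L,CDS,NADH dehydrogenase subunit 4L,
nad5,CDS,nad5,
nad5,CDS,NADH dehydrogenase subunit 5,
nad6,CDS,nad6,
nad6,CDS,NADH dehydrogenase subunit 6,
nad7,CDS,nad7,
nad7,CDS,NADH dehydrogenase subunit 7,
nad9,CDS,nad9,
nad9,CDS,NADH dehydrogenase subunit 9,
rps3,CDS,rps3,
rps3,CDS,ribosomal protein S3,
rps12,CDS,rps12,
rps12,CDS,ribosomal protein S12,
rpl16,CDS,rpl16,
rpl16,CDS,ribosomal protein L16,
rrn5,rRNA,5S ribosomal RNA,
rrn5,rRNA,rrn5,
rrn18,rRNA,18S ribosomal RNA,
rrn18,rRNA,rrn18,
rrn26,rRNA,26S ribosomal RNA,
rrn26,rRNA,rrn26,
nad1_intron2,intron,nad1,2
cox2_intron1,intron,cox2,1
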