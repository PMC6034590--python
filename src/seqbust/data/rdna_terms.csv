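Locus,Type,Name,IntronExonNumber
18S,rRNA,18S ribosomal RNA,
18S,rRNA,18S rRNA,
18S,rRNA,18S,
18S,rRNA,small subunit ribosomal RNA,
18S,rRNA,SSU rRNA,
18S,rRNA,18S small subunit ribosomal RNA,
5_8S,rRNA,5.8S ribosomal RNA,
5_8S,rRNA,5.8S rRNA,
5_8S,rRNA,5.8S,
28S,rRNA,28S ribosomal RNA,
28S,rRNA,28S rRNA,
28S,rRNA,28S,
28S,rRNA,large subunit ribosomal RNA,
28S,rRNA,LSU rRNA,
28S,rRNA,28S large subunit ribosomal RNA,
ITS1,misc_RNA,internal transcribed spacer 1,
ITS1,misc_RNA,ITS1,
ITS1,misc_RNA,ITS 1,
ITS1,misc_RNA,internal transcribed spacer 1 ITS1,
ITS2,misc_RNA,internal transcribed spacer 2,
ITS2,misc_RNA,ITS2,
ITS2,misc_RNA,ITS 2,
ITS2,misc_RNA,internal transcribed spacer 2 ITS2,
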