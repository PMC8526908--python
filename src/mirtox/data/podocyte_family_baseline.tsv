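family	rpkm	essential_target_genes
let-7	83700	Gng5;Apbb3;Nras;Eif4g2;Timm17b;Gas7;Snx5;Tgfbr3;Swt1;Lgr4;Arhgap28;Ptprd
miR-26-5p	37646	App;Tob1;Serbp1;Ubn2;Plod2;Pura;Vdac1;Trib2;Twf1;Ptp4a1;Eif4g2;Ywhae;Bbx;Srgap1;Matr3;Gsk3b
miR-10a	9938	Fnbp1l;Bbx;Dusp3;Clasp2;Son;Ctdspl;Wapal;Zdhhc21;Aff4
miR-486-5p	8870	Tob1;Prr2c;Znf207;Dynll1
miR-22-3p	8185	Lin7c;Ywhaz;Npnt;Wapal;Trib2;Magi2;Apbb2;Csnk1a1;Nras;Pnisr;Pcnp;Zbtb20;Ftl
miR-27-3p	5951	Kiaa1109;Apaf1;Aff4;Nfia;Pura;Khsrp;Cd2ap;Nbeal1;Nedd4;Qki;Tgfbr3;Lpl;Atp6v1a;Lpin2
miR-30-5p	5352	Twf1;Zdhhc21;Reep3;Pbrm1;Lrrc58;Qki;Ptp4a1;Vim;Nedd4;Ywhaz;Lin7c;Csnk1a1;Nfia;Ssbp2;Jak1;Smim14
miR-125-5p	5689	Podxl;Osbpl9;C6orf47;Enpep;Gpc1;Wdr1;Trib2;Dazap2;Foxn3;Reep3;Qki
miR-99-5p	3802	Ctdspl;Trib2
miR-191-5p	1883	Chmp5;Nfia;Lrrc8a;Tjp1;Fubp3
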