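# Core cell-cycle phase gene sets (mouse symbols): 43 G1/S and 54 G2/M genes.
# Tab-separated: phase<TAB>symbol.  User-replaceable via CycleGeneSets.
G1/S	Mcm5
G1/S	Pcna
G1/S	Tyms
G1/S	Fen1
G1/S	Mcm2
G1/S	Mcm4
G1/S	Rrm1
G1/S	Ung
G1/S	Gins2
G1/S	Mcm6
G1/S	Cdca7
G1/S	Dtl
G1/S	Prim1
G1/S	Uhrf1
G1/S	Mlf1ip
G1/S	Hells
G1/S	Rfc2
G1/S	Rpa2
G1/S	Nasp
G1/S	Rad51ap1
G1/S	Gmnn
G1/S	Wdr76
G1/S	Slbp
G1/S	Ccne2
G1/S	Ubr7
G1/S	Pold3
G1/S	Msh2
G1/S	Atad2
G1/S	Rad51
G1/S	Rrm2
G1/S	Cdc45
G1/S	Cdc6
G1/S	Exo1
G1/S	Tipin
G1/S	Dscc1
G1/S	Blm
G1/S	Casp8ap2
G1/S	Usp1
G1/S	Clspn
G1/S	Pola1
G1/S	Chaf1b
G1/S	Brip1
G1/S	E2f8
G2/M	Hmgb2
G2/M	Cdk1
G2/M	Nusap1
G2/M	Ube2c
G2/M	Birc5
G2/M	Tpx2
G2/M	Top2a
G2/M	Ndc80
G2/M	Cks2
G2/M	Nuf2
G2/M	Cks1b
G2/M	Mki67
G2/M	Tmpo
G2/M	Cenpf
G2/M	Tacc3
G2/M	Fam64a
G2/M	Smc4
G2/M	Ccnb2
G2/M	Ckap2l
G2/M	Ckap2
G2/M	Aurkb
G2/M	Bub1
G2/M	Kif11
G2/M	Anp32e
G2/M	Tubb4b
G2/M	Gtse1
G2/M	Kif20b
G2/M	Hjurp
G2/M	Cdca3
G2/M	Hn1
G2/M	Cdc20
G2/M	Ttk
G2/M	Cdc25c
G2/M	Kif2c
G2/M	Rangap1
G2/M	Ncapd2
G2/M	Dlgap5
G2/M	Cdca2
G2/M	Cdca8
G2/M	Ect2
G2/M	Kif23
G2/M	Hmmr
G2/M	Aurka
G2/M	Psrc1
G2/M	Anln
G2/M	Lbr
G2/M	Ckap5
G2/M	Cenpe
G2/M	Ctcf
G2/M	Nek2
G2/M	G2e3
G2/M	Gas2l3
G2/M	Cbx5
G2/M	Cenpa
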