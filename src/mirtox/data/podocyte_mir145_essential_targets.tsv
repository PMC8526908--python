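symbol	description	mean_rpkm	context_score
ACTB	actin, beta	13889.86	-0.43
GNB1	guanine nucleotide-binding protein (G protein), beta polypeptide 1	2439.721	-0.15
ST13	suppression of tumorigenicity 13	2106.819	-0.04
DPYSL2	dihydropyrimidinase-like 2	1419.238	-0.05
EIF4A2	eukaryotic translation initiation factor 4A2	1082.761	-0.14
Podxl	podocalyxin-like	1050.493	-0.18
SET	SET nuclear proto-oncogene	951.0317	-0.11
QKI	QKI, KH domain containing, RNA binding	776.3372	-0.12
TMOD3	tropomodulin 3 (ubiquitous)	531.727	-0.24
SKP1	S-phase kinase-associated protein 1	503.8126	-0.08
ARHGAP24	Rho GTPase-activating protein 24	452.6906	-0.23
MPP5	membrane protein, palmitoylated 5 (MAGUK p55 subfamily member 5)	270.9088	-0.35
NRAS	neuroblastoma RAS viral (v-ras) oncogene homolog	249.8165	-0.15
ACSL4	acyl-CoA synthetase long-chain family member 4	246.0129	-0.09
EPB41L5	erythrocyte membrane protein band 4.1 like 5	214.3441	-0.24
ARHGAP28	Rho GTPase-activating protein 28	199.0145	-0.07
SRGAP1	SLIT-ROBO Rho GTPase-activating protein 1	172.8949	-0.31
CORO2B	coronin, actin-binding protein, 2B	172.8764	-0.19
DENND5B	DENN/MADD domain containing 5B	152.5768	-0.12
SPOP	speckle-type POZ protein	146.9724	-0.43
OGT	O-linked N-acetylglucosamine (GlcNAc) transferase	137.9184	-0.05
PLCE1	phospholipase C, epsilon 1	128.7123	-0.29
MAGI2	membrane-associated guanylate kinase, WW and PDZ domain containing 2	120.5446	-0.33
PDCD4	programmed cell death 4 (neoplastic transformation inhibitor)	109.5968	-0.18
NFIA	nuclear factor I/A	97.51652	-0.1
Dst	dystonin	97.29717	-0.33
NFE2L1	nuclear factor, erythroid 2-like 1	56.95308	-0.17
UBN2	ubinuclein 2	44.89126	-0.1
PURA	purine-rich element binding protein A	35.38958	-0.12
SIK2	salt-inducible kinase 2	32.43537	-0.12
ERMP1	endoplasmic reticulum metallopeptidase 1	12.50254	-0.1
HELLS	helicase, lymphoid-specific	1.301073	-0.2
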