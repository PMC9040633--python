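#! id=acetogen_core
#! objective=EX_biomass
#! atp_maintenance=ATPM
#! named_products=bdo:EX_bdoh,co2:EX_co2,acetate:EX_ac,ethanol:EX_etoh,biomass:EX_biomass
#! metabolite co formula=CO carbon=1 name="carbon monoxide"
#! metabolite co2 formula=CO2 carbon=1 name="carbon dioxide"
#! metabolite h2 formula=H2 carbon=0 name="dihydrogen"
#! metabolite h2o formula=H2O carbon=0 name="water"
#! metabolite h formula=H carbon=0 name="proton (cytosolic)"
#! metabolite h_ext formula=H carbon=0 name="proton (periplasmic, chemiosmotic)"
#! metabolite pi formula=HO4P carbon=0 name="phosphate"
#! metabolite amp formula=C10H12N5O7P carbon=10 name="AMP"
#! metabolite adp formula=C10H12N5O10P2 carbon=10 name="ADP"
#! metabolite atp formula=C10H12N5O13P3 carbon=10 name="ATP"
#! metabolite nad formula=C21H26N7O14P2 carbon=21 name="NAD+"
#! metabolite nadh formula=C21H27N7O14P2 carbon=21 name="NADH"
#! metabolite nadp formula=C21H25N7O17P3 carbon=21 name="NADP+"
#! metabolite nadph formula=C21H26N7O17P3 carbon=21 name="NADPH"
#! metabolite Fd_ox formula=Fd carbon=0 name="oxidized ferredoxin"
#! metabolite Fd_red formula=Fd carbon=0 name="reduced ferredoxin"
#! metabolite coa formula=C21H32N7O16P3S carbon=21 name="coenzyme A"
#! metabolite accoa formula=C23H34N7O17P3S carbon=23 name="acetyl-CoA"
#! metabolite actp formula=C2H4O5P carbon=2 name="acetyl phosphate"
#! metabolite ac formula=C2H3O2 carbon=2 name="acetate"
#! metabolite ac_ext formula=C2H3O2 carbon=2 name="acetate (external)"
#! metabolite acald formula=C2H4O carbon=2 name="acetaldehyde"
#! metabolite etoh formula=C2H6O carbon=2 name="ethanol"
#! metabolite etoh_ext formula=C2H6O carbon=2 name="ethanol (external)"
#! metabolite pyr formula=C3H3O3 carbon=3 name="pyruvate"
#! metabolite lac-L formula=C3H5O3 carbon=3 name="L-lactate"
#! metabolite acltt formula=C5H7O4 carbon=5 name="(S)-2-acetolactate"
#! metabolite actn formula=C4H8O2 carbon=4 name="acetoin"
#! metabolite bdoh formula=C4H10O2 carbon=4 name="2,3-butanediol"
#! metabolite for formula=CHO2 carbon=1 name="formate"
#! metabolite thf formula=C19H23N7O6 carbon=19 name="tetrahydrofolate"
#! metabolite 10fthf formula=C20H23N7O7 carbon=20 name="10-formyl-THF"
#! metabolite methf formula=C20H22N7O6 carbon=20 name="5,10-methenyl-THF"
#! metabolite mlthf formula=C20H23N7O6 carbon=20 name="5,10-methylene-THF"
#! metabolite 5mthf formula=C20H25N7O6 carbon=20 name="5-methyl-THF"
#! metabolite nh3 formula=NH4 carbon=0 name="ammonia/ammonium"
#! metabolite glu-L formula=C5H8NO4 carbon=5 name="L-glutamate"
#! metabolite gln-L formula=C5H10N2O3 carbon=5 name="L-glutamine"
#! metabolite akg formula=C5H4O5 carbon=5 name="2-oxoglutarate"
#! metabolite oaa formula=C4H2O5 carbon=4 name="oxaloacetate"
#! metabolite cit formula=C6H5O7 carbon=6 name="citrate"
#! metabolite icit formula=C6H5O7 carbon=6 name="isocitrate"
#! metabolite asp-L formula=C4H6NO4 carbon=4 name="L-aspartate"
#! metabolite aspsa formula=C4H7NO3 carbon=4 name="L-aspartate 4-semialdehyde"
#! metabolite hom-L formula=C4H9NO3 carbon=4 name="L-homoserine"
#! metabolite thr-L formula=C4H9NO3 carbon=4 name="L-threonine"
#! metabolite ala-L formula=C3H7NO2 carbon=3 name="L-alanine"
#! metabolite succ formula=C4H4O4 carbon=4 name="succinate"
#! metabolite fum formula=C4H2O4 carbon=4 name="fumarate"
#! metabolite mal-L formula=C4H4O5 carbon=4 name="L-malate"
#! metabolite pep formula=C3H2O6P carbon=3 name="phosphoenolpyruvate"
#! metabolite 2pg formula=C3H4O7P carbon=3 name="2-phospho-D-glycerate"
#! metabolite 3pg formula=C3H4O7P carbon=3 name="3-phospho-D-glycerate"
#! metabolite 13dpg formula=C3H4O10P2 carbon=3 name="1,3-bisphospho-D-glycerate"
#! metabolite g3p formula=C3H5O6P carbon=3 name="glyceraldehyde 3-phosphate"
#! metabolite dhap formula=C3H5O6P carbon=3 name="dihydroxyacetone phosphate"
#! metabolite fdp formula=C6H11O12P2 carbon=6 name="D-fructose 1,6-bisphosphate"
#! metabolite f6p formula=C6H11O9P carbon=6 name="D-fructose 6-phosphate"
#! metabolite f1p formula=C6H11O9P carbon=6 name="D-fructose 1-phosphate"
#! metabolite fru formula=C6H12O6 carbon=6 name="D-fructose"
#! metabolite g6p formula=C6H11O9P carbon=6 name="D-glucose 6-phosphate"
#! metabolite biomass formula=- carbon=38 name="biomass (lumped, 38 C per unit)"
EX_co	co <=>	-50	0
EX_co2	co2 <=>	-50	1000
EX_h2	h2 <=>	-50	1000
EX_h2o	h2o <=>	-1000	1000
EX_h	h <=>	-1000	1000
EX_ac	ac_ext ->	0	1000
EX_etoh	etoh_ext ->	0	1000
EX_bdoh	bdoh ->	0	1000
EX_lac	lac-L ->	0	1000
EX_biomass	biomass ->	0	1000
EX_thf	thf <=>	-1/20	1000
EX_nh3	nh3 <=>	-10	1000
ACT	ac <=> ac_ext	-1000	1000
ETOHt	etoh <=> etoh_ext	-1000	1000
CODH	co + h2o + Fd_ox <=> co2 + 2 h + Fd_red	-1000	1000
FDH	nadph + 2 co2 + h + Fd_red <=> nadp + 2 for + Fd_ox	-1000	1000
FTHFLi	atp + for + thf -> adp + pi + 10fthf	0	1000
MTHFC	10fthf + h <=> methf + h2o	-1000	1000
MTHFD	methf + nadph <=> mlthf + nadp	-1000	1000
MTHFR	mlthf + nadh + h -> 5mthf + nad	0	1000
ACS	5mthf + co + coa <=> accoa + thf	-1000	1000
HYDFDNy	nadp + Fd_ox + 2 h2 -> nadph + 3 h + Fd_red	0	1000
HYDFDNx	nad + Fd_ox + 2 h2 -> nadh + 3 h + Fd_red	0	1000
NFN	Fd_red + nadh + 2 nadp + h <=> Fd_ox + nad + 2 nadph	-1000	1000
RNF	nad + 3 h + Fd_red <=> nadh + 2 h_ext + Fd_ox	-1000	1000
ATPS	adp + pi + 4 h_ext -> atp + h2o + 3 h	0	1000
ATPM	atp + h2o -> adp + pi + h	0	1000
PTA	pi + accoa + h <=> coa + actp	-1000	1000
ACK	adp + actp <=> atp + ac + h	-1000	1000
ACAFDOR	ac + 3 h + Fd_red <=> h2o + acald + Fd_ox	-1000	1000
ACALDy	acald + nadp + coa <=> accoa + nadph + h	-1000	1000
ALCDx	nadh + h + acald <=> nad + etoh	-1000	1000
ALCDy	nadph + h + acald -> nadp + etoh	0	1000
LDH	pyr + nadh + h <=> lac-L + nad	-1000	1000
PFOR	coa + pyr + Fd_ox <=> co2 + accoa + h + Fd_red	-1000	1000
PFL	pyr + coa -> accoa + for	0	1000
ACLS	2 pyr + h <=> co2 + acltt	-1000	1000
ACLDC	h + acltt <=> co2 + actn	-1000	1000
BTDDx	nad + bdoh <=> nadh + h + actn	-1000	1000
PPS	pyr + atp + h2o -> pep + amp + pi + 2 h	0	1000
PYK	pep + adp + h -> pyr + atp	0	1000
ADK1	amp + atp <=> 2 adp	-1000	1000
ENO	2pg <=> pep + h2o	-1000	1000
PGM	2pg <=> 3pg	-1000	1000
PGK	3pg + atp <=> 13dpg + adp	-1000	1000
GAPD	g3p + nad + pi <=> 13dpg + nadh + h	-1000	1000
TPI	dhap <=> g3p	-1000	1000
FBA	fdp <=> dhap + g3p + h	-1000	1000
FBP	h2o + fdp <=> pi + h + f6p	-1000	1000
FRUK	f1p + atp -> fdp + adp	0	1000
FRUpts	fru + pep -> f1p + pyr	0	1000
PGI	f6p <=> g6p	-1000	1000
PC	pyr + co2 + atp + h2o -> oaa + adp + pi + 2 h	0	1000
PEPCK	oaa + atp -> pep + co2 + adp	0	1000
CS	accoa + h2o + oaa -> cit + coa + h	0	1000
ACONT	cit <=> icit	-1000	1000
ICDHyr	icit + nadp <=> akg + co2 + nadph	-1000	1000
GLUD	h2o + nadp + glu-L <=> nadph + nh3 + akg + h	-1000	1000
GLNS	glu-L + nh3 + atp -> gln-L + adp + pi + h	0	1000
GOGAT	gln-L + akg + nadph + h -> 2 glu-L + nadp	0	1000
ASPTA	oaa + glu-L <=> asp-L + akg	-1000	1000
ASAD	asp-L + atp + nadph + h -> aspsa + adp + pi + nadp	0	1000
HSDH	nad + hom-L <=> nadh + h + aspsa	-1000	1000
THRS	hom-L + atp + h2o -> thr-L + adp + pi + h	0	1000
ALATA	pyr + glu-L <=> ala-L + akg	-1000	1000
MDH	mal-L + nad <=> oaa + nadh + h	-1000	1000
FUM	fum + h2o <=> mal-L	-1000	1000
FRD	fum + nadh + h -> succ + nad	0	1000
NADK	nad + atp -> nadp + adp + h	0	1000
BIOMASS	5/2 accoa + 2 pyr + 3/4 oaa + 6/5 glu-L + 3/10 gln-L + 3/5 ala-L + 1/2 asp-L + 2/5 thr-L + 1/10 hom-L + 1/5 succ + 3/4 f6p + 1/2 g6p + 2/5 3pg + 1/5 pep + 1/5 g3p + 90 atp + 90 h2o + 4 nadph -> 90 adp + 1841/20 pi + 4 nadp + 5/2 coa + biomass	0	1000
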