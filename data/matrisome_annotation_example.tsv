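gene_symbol	division	category
FN1	core_matrisome	ECM_glycoproteins
POSTN	core_matrisome	ECM_glycoproteins
TNC	core_matrisome	ECM_glycoproteins
LTBP3	core_matrisome	ECM_glycoproteins
SNED1	core_matrisome	ECM_glycoproteins
NID1	core_matrisome	ECM_glycoproteins
LAMA5	core_matrisome	ECM_glycoproteins
LAMB1	core_matrisome	ECM_glycoproteins
LAMC1	core_matrisome	ECM_glycoproteins
VTN	core_matrisome	ECM_glycoproteins
FGA	core_matrisome	ECM_glycoproteins
FGB	core_matrisome	ECM_glycoproteins
FGG	core_matrisome	ECM_glycoproteins
COL1A1	core_matrisome	collagens
COL1A2	core_matrisome	collagens
COL3A1	core_matrisome	collagens
COL4A1	core_matrisome	collagens
COL5A1	core_matrisome	collagens
COL6A1	core_matrisome	collagens
COL6A2	core_matrisome	collagens
COL6A3	core_matrisome	collagens
COL18A1	core_matrisome	collagens
HSPG2	core_matrisome	proteoglycans
VCAN	core_matrisome	proteoglycans
BGN	core_matrisome	proteoglycans
DCN	core_matrisome	proteoglycans
ANXA2	matrisome_associated	ECM_affiliated
LGALS1	matrisome_associated	ECM_affiliated
LGALS3	matrisome_associated	ECM_affiliated
PLG	matrisome_associated	ECM_regulators
F2	matrisome_associated	ECM_regulators
F13A1	matrisome_associated	ECM_regulators
TGM2	matrisome_associated	ECM_regulators
LOXL2	matrisome_associated	ECM_regulators
CTSB	matrisome_associated	ECM_regulators
SERPINE2	matrisome_associated	ECM_regulators
EGLN1	matrisome_associated	secreted_factors
S100A2	matrisome_associated	secreted_factors
S100A10	matrisome_associated	secreted_factors
ANGPTL4	matrisome_associated	secreted_factors
IGFBP4	matrisome_associated	secreted_factors
CYR61	matrisome_associated	secreted_factors
CTGF	matrisome_associated	secreted_factors
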