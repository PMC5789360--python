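Proteoglycans in cancer	EMT-related	ANK2	FASLG	HSPG2	PTPN11	STAT3	VEGFA
HIF-1 signaling pathway	EMT-related	ARNT	STAT3	VEGFA
FoxO signaling pathway	EMT-related	FASLG	SMAD4	STAT3
ECM-receptor interaction	EMT-related	HSPG2	LAMA2
Adherens junction	EMT-related	CTNNA3	SMAD4
Ras signaling pathway	EMT-related	FASLG	PTPN11	VEGFA
Jak-STAT signaling pathway	EMT-related	PTPN11	STAT3
PI3K-AKT signaling pathway	EMT-related	FASLG	LAMA2	VEGFA
Focal adhesion	EMT-related	LAMA2	VEGFA
VEGF signaling pathway	EMT-related	VEGFA
TGF-beta signaling pathway	EMT-related	SMAD4
MAPK signaling pathway	EMT-related	FASLG	MAP3K20
Wnt signaling pathway	EMT-related	SMAD4
Regulation of actin cytoskeleton	EMT-related	SCIN
Metabolism	metabolism (synthetic fixture)	CYP11B1	PDE4D	ALDH3A1	GPX2	PLA2G4F	ADCY4	AKR1C2	NT5E	CYP2C8	PDE1C	HK2	GLS2	UGT1A6
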