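# Curated protein sets for the budding-yeast prion analysis.
# KP: well-characterized amyloid-based prions (10).
# EPD_EXTRA: proteins added to the KPs to form the Experimental Prionogenic
#   Domain (EPD) set, shown to be likely prions via the SUP35C fusion assay
#   plus in vivo amyloid evidence (17; EPD = KP + EPD_EXTRA = 27).
# EPN: Experimental Prion Negatives, proteins that failed all prion-activity
#   assays (18).
# set	accession	gene
KP	P05453	SUP35
KP	P07884	MOD5
KP	P09547	SWI1
KP	P14922	CYC8
KP	P23202	URE2
KP	P25367	RNQ1
KP	P32432	SFP1
KP	Q08972	NEW1
KP	P54785	MOT3
KP	Q02629	NUP100
EPD_EXTRA	P14907	NSP1
EPD_EXTRA	P18494	GLN3
EPD_EXTRA	P32588	PUB1
EPD_EXTRA	P32770	NRP1
EPD_EXTRA	P38180	YBL081W
EPD_EXTRA	P38216	YBR016W
EPD_EXTRA	P38429	SAP30
EPD_EXTRA	P38691	KSP1
EPD_EXTRA	P40070	LSM4
EPD_EXTRA	P40356	PGD1
EPD_EXTRA	P53894	CBK1
EPD_EXTRA	Q05166	ASM4
EPD_EXTRA	Q08925	MRN1
EPD_EXTRA	Q12139	YPR022C
EPD_EXTRA	Q12221	PUF2
EPD_EXTRA	Q12224	RLM1
EPD_EXTRA	Q12361	GPR1
EPN	P11746	MCM1
EPN	P14680	YAK1
EPN	P22082	SNF2
EPN	P23291	YCK1
EPN	P25339	PUF4
EPN	P32505	NAB2
EPN	P32896	PDC2
EPN	P32900	SKG6
EPN	P38080	AKL1
EPN	P39081	PCF11
EPN	P43572	EPL1
EPN	P45978	SCD6
EPN	P53617	NRD1
EPN	P53829	CAF40
EPN	Q03761	TAF12
EPN	Q05785	ENT2
EPN	Q06251	YLR177W
EPN	Q12124	MED2
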