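# drug_name	drug_class
pembrolizumab	PD1i
nivolumab	PD1i
atezolizumab	PDL1i
afatinib	EGFR_TKI
osimertinib	EGFR_TKI
gefitinib	EGFR_TKI
erlotinib	EGFR_TKI
ceritinib	ALK_TKI
crizotinib	ALK_TKI
lorlatinib	ALK_TKI
alectinib	ALK_TKI
bevacizumab	VEGFi
gemcitabine	cytotoxic
amrubicin	cytotoxic
docetaxel	cytotoxic
paclitaxel	cytotoxic
cisplatin	cytotoxic
pemetrexed	cytotoxic
irinotecan	cytotoxic
carboplatin	cytotoxic
etoposide	cytotoxic
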