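# Demonstration profile metadata: domain, model length, GA threshold (bits), coverage threshold.
# The zf-C2H2 / HLH gathering thresholds and the bZIP_AUREO / bZIP_CDD
# coverage cutoffs are the calibrated values used in production; the
# remaining rows carry plausible demonstration values.
zf-C2H2	23	9.45	-
HLH	54	14.00	-
AP2	56	16.00	-
bZIP_1	66	20.00	-
bZIP_2	41	22.00	-
bZIP_AUREO	120	25.00	0.75
bZIP_CDD	80	25.00	0.50
HMG_box	68	17.00	-
PHD	52	17.00	-
CBFD_NFYB_HMF	65	25.00	-
SNF2_N	290	24.00	-
HSF_DNA-bind	97	21.00	-
Homeobox	57	18.00	-
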