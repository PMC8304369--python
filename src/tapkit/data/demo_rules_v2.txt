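# Demonstration TAP family rule catalogue, previous rule generation:
# no bZIP_AUREO / bZIP_CDD satellite families, and no HMG_box vetoes
# on PHD / CCAAT_HAP5 / SWI/SNF_SNF2 — multi-domain HMG proteins are
# therefore pulled away by whichever competitor scores the stronger
# E-value.
bZIP; bZIP_1; should
bZIP; class; TF
C2H2; zf-C2H2; should
C2H2; class; TF
AP2/EREBP; AP2; should
AP2/EREBP; class; TF
bHLH; HLH; should
bHLH; class; TF
HSF; HSF_DNA-bind; should
HSF; class; TF
HMG; HMG_box; should
HMG; class; TF
PHD; PHD; should
PHD; class; TR
CCAAT_HAP5; CBFD_NFYB_HMF; should
CCAAT_HAP5; class; TF
SWI/SNF_SNF2; SNF2_N; should
SWI/SNF_SNF2; class; TR
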