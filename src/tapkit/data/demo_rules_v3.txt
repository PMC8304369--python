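# Demonstration TAP family rule catalogue (current rule generation).
# Dialect: family; domain; should | should not   — plus optional
#          family; class; TF|TR|PT class annotations.
#
# bZIP and its algal-specific satellite families. The bZIP_AUREO and
# bZIP_CDD profiles sharpen the definition of bZIP-like proteins in
# algae; helix-loop-helix or homeodomain co-occurrence disqualifies.
bZIP; bZIP_1; should
bZIP; class; TF
bZIPAUREO; bZIP_AUREO; should
bZIPAUREO; HLH; should not
bZIPAUREO; Homeobox; should not
bZIPAUREO; class; TF
bZIPCDD; bZIP_CDD; should
bZIPCDD; HLH; should not
bZIPCDD; Homeobox; should not
bZIPCDD; class; TF

C2H2; zf-C2H2; should
C2H2; class; TF
AP2/EREBP; AP2; should
AP2/EREBP; class; TF
bHLH; HLH; should
bHLH; class; TF
HSF; HSF_DNA-bind; should
HSF; class; TF

# HMG and the families that compete with it on multi-domain proteins.
# Proteins carrying an HMG_box alongside a (often stronger-scoring)
# PHD / NF-Y / SNF2 domain belong with HMG, so the competitors carry
# an HMG_box veto.
HMG; HMG_box; should
HMG; class; TF
PHD; PHD; should
PHD; HMG_box; should not
PHD; class; TR
CCAAT_HAP5; CBFD_NFYB_HMF; should
CCAAT_HAP5; HMG_box; should not
CCAAT_HAP5; class; TF
SWI/SNF_SNF2; SNF2_N; should
SWI/SNF_SNF2; HMG_box; should not
SWI/SNF_SNF2; class; TR
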