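# Synthetic example panel of profibrotic / extracellular-matrix genes, one
# symbol per line, for use as the user-supplied gene list consumed by the
# heatmap/panel-profiling helpers. This is an ILLUSTRATIVE list assembled from
# well-known fibrosis biology (collagens, TGF-beta/SMAD axis, matrix
# remodelling); it is NOT the attested 70-gene reference panel, which users
# should supply from their own curation.
COL1A1
COL1A2
COL3A1
COL5A1
FN1
TGFB1
TGFB2
TGFB3
SMAD1
SMAD3
SMAD4
ACTA2
CTGF
TIMP1
TIMP2
MMP2
MMP9
IL6
AGT
FOS
CCL2
ELN
LOX
PDGFA
PDGFB
SERPINE1
THBS1
VIM
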