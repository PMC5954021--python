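gene	arm
VIM	mesenchymal
CDH2	mesenchymal
FN1	mesenchymal
ZEB1	mesenchymal
ZEB2	mesenchymal
SNAI1	mesenchymal
SNAI2	mesenchymal
TWIST1	mesenchymal
FOXC2	mesenchymal
MMP2	mesenchymal
MMP9	mesenchymal
SPARC	mesenchymal
COL1A1	mesenchymal
COL1A2	mesenchymal
COL3A1	mesenchymal
COL5A2	mesenchymal
FBN1	mesenchymal
TNC	mesenchymal
WNT5A	mesenchymal
ITGB6	mesenchymal
CDH1	epithelial
DSP	epithelial
OCLN	epithelial
CLDN3	epithelial
CLDN4	epithelial
CLDN7	epithelial
KRT8	epithelial
KRT18	epithelial
KRT19	epithelial
EPCAM	epithelial
ESRP1	epithelial
ESRP2	epithelial
GRHL2	epithelial
CRB3	epithelial
TJP1	epithelial
MUC1	epithelial
CDH3	epithelial
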