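# Fixed vocabulary for synthetic GO-term labels.
# One token per line; lines starting with '#' are ignored.
acetylation
activation
adhesion
angiogenesis
apoptotic
assembly
biosynthetic
cell
chondrocyte
chromatin
compound
cytokine
development
differentiation
endopeptidase
epigenetic
erythrocyte
granulocyte
growth
hematopoietic
hemopoiesis
homeostasis
immune
kinase
leukocyte
lymphocyte
maturation
membrane
metabolic
migration
morphogenesis
myeloid
negative
nuclear
organization
pathway
phosphate-containing
phosphorylation
positive
process
progenitor
proliferation
protein
receptor
regulation
remodeling
response
signaling
stem
stimulus
transcription
transduction
transport
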