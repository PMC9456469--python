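# Default curated keyword list for GO-term selection.
# Expert curation is deliberately explicit configuration: override freely.
# One keyword per line; matched as whole tokens after label cleaning.
acetylation
acylation
angiogenesis
chondrocyte
chromatin
cytokine
differentiation
endopeptidase
epigenetic
growth
hematopoietic
hemopoiesis
immune
kinase
leukocyte
myeloid
p53
phosphorylation
stem
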