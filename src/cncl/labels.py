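"""Phenotype label constants shared across modules."""

CSM = "CS/M"   # cancer-stem-cell-like and mesenchymal
NSE = "NS/E"   # non-cancer-stem-cell-like and epithelial
INTERMEDIARY = "I"

PHENOTYPES = (CSM, NSE, INTERMEDIARY)
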