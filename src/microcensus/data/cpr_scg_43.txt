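# 43-marker single-copy gene set for CPR-style genome QC.
# Ribosomal-protein-centric reconstruction: CPR genomes lack several
# universal bacterial markers (e.g. many tRNA synthetases), so the set is
# dominated by ribosomal proteins plus three near-universal information/
# secretion genes. One identifier per line; swap in any set you prefer.
rpL2
rpL3
rpL4
rpL5
rpL6
rpL10
rpL11
rpL13
rpL14
rpL15
rpL16
rpL17
rpL18
rpL19
rpL20
rpL21
rpL22
rpL23
rpL24
rpL27
rpL29
rpL30
rpS2
rpS3
rpS4
rpS5
rpS6
rpS7
rpS8
rpS9
rpS10
rpS11
rpS12
rpS13
rpS15
rpS16
rpS17
rpS18
rpS19
rpS20
infB
secY
ffh
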