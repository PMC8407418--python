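# Annotation-product synonyms mapped to cyo operon gene labels.
# Matching is exact after case-folding; extend freely for your annotator.
# synonym	label
cyoA	cyoA
cyoB	cyoB
cyoC	cyoC
cyoD	cyoD
cyoE	cyoE
cytochrome o ubiquinol oxidase subunit II	cyoA
ubiquinol oxidase subunit 2	cyoA
cytochrome o ubiquinol oxidase subunit I	cyoB
cytochrome bo3 ubiquinol oxidase subunit 1	cyoB
ubiquinol oxidase subunit 1	cyoB
cytochrome o ubiquinol oxidase subunit III	cyoC
ubiquinol oxidase subunit 3	cyoC
cytochrome o ubiquinol oxidase subunit IV	cyoD
ubiquinol oxidase subunit 4	cyoD
protoheme IX farnesyltransferase	cyoE
heme O synthase	cyoE
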