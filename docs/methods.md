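# Methods

`microcensus` quantifies rare, ultrasmall microbes (CPR bacteria, DPANN
archaea) in paired size-fractionated soil metagenomes: a *bulk* sample
(total community shotgun sequencing) and a *concentrate* sample (particles
passing a 0.2-µm filter, DNase-treated, so dominated by ultrasmall cells).
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic-data tests do and do not demonstrate.

## Coverage and abundance model

For a scaffold of length L with per-base depths d₁…d_L (positions missing
from a samtools-depth file count as zero):

- **mean depth** c = Σᵢ dᵢ / L;
- **breadth** = |{i : dᵢ ≥ t}| / L with threshold t = 1 by default. The
  study whose analysis chain this reproduces does not state a depth
  threshold for breadth; t is exposed as `breadth_min_depth`.

Two relative-abundance normalisations are kept explicit because different
downstream questions need different ones:

- **base fraction** of unit g in a sample: c_g·L_g / Σ_h c_h·L_h — the
  fraction of sequenced bases attributable to g. This is what read mapping
  measures directly; scaffold-level enrichment uses it.
- **cell fraction** (bins only): c_g / Σ_h c_h over bins, where c_g is the
  length-weighted bin mean depth. One cell contributes one genome copy's
  worth of depth regardless of genome size, so depth ratios approximate
  cell ratios. The census uses it.

Bins aggregate scaffolds length-weighted: bin depth = Σ cᵢLᵢ / Σ Lᵢ, bin
breadth = Σ coveredᵢ / Σ Lᵢ. Both abundance flavours sum to one per sample
(tolerance 1e-9); an all-zero sample is flagged undefined rather than
reported as 0/0.

## Enrichment factor

E(g) = base fraction of g in concentrate / base fraction in bulk. Rare
organisms are routinely *absent* from the bulk sample, so a zero bulk
abundance is handled with an explicit one-read detection floor,
read_length / total_mapped_bases, never a silent pseudocount: the result
is reported as a lower bound with a flag, and per-bin summaries
(median/quartiles, matching a boxplot presentation and robust to
fragmented-scaffold noise) count lower bounds separately and never average
them in. Whether a published 100–1,000× figure refers to per-scaffold
values or per-genome medians is ambiguous; both are reported.

## Cell census

Model A (default): cells/g = cell_fraction × N_total with N_total = 10⁹
cells per gram of soil, the standard order-of-magnitude estimate for
soil. It reproduces the arithmetic chain exactly: a lineage at 10⁻⁵ % of
cells is a fraction of 10⁻⁷, i.e. 100 cells/g. Model B converts a DNA-mass
share instead: copies/g = yield_g × base_fraction / (L × m_bp) with
m_bp = 650 g mol⁻¹ bp⁻¹ / N_A = 1.079·10⁻²¹ g/bp, under one genome copy
per cell (polyploidy out of scope). Estimates below 1 cell/g are reported
as-is with a `sub_unity` flag. Both models are linear in abundance.

## Genome QC

Completeness = % of a single-copy-gene set present ≥1 time; contamination
(default) = % of the set present ≥2 times — a duplication notion
restricted to the set, as CheckM uses; a copies-minus-one variant
(`excess_copies`) is configurable because the source analyses do not pin
the definition down. Retention uses *strict* inequalities
(completeness > 70, contamination < 10), matching the ">70 % complete"
and "<10 % contamination" phrasing: a bin at exactly 70/10 is rejected.
The shipped 43-marker set is a ribosomal-protein-centric reconstruction
suitable for CPR genomes (which lack several universal markers); it is an
editable text file and any set can be substituted. Marker *detection*
(HMM search) is upstream's job; input is a gene-hit table.

## Metabolic profile

Identifier-based matching (gene symbols, EC numbers, product strings;
exact after case-folding) of marker aliases (TIM, GAPDH, PGK, NADH
dehydrogenase, ctaB, PPA, sdhA) and flat pathway gene sets (F-type ATPase,
TCA, amino-acid/lipid/purine/pyrimidine biosynthesis). Pathway
completeness is simply % of members present — no KEGG-style boolean module
logic. The shipped pathway memberships are reconstructions of commonly
used definitions and are marked as such in the panel file.

## In-silico PCR

A primer position matches a subject base iff the base is in the primer
IUPAC code's expansion. Subject N matches nothing (counts as a mismatch);
other subject ambiguity codes match iff expansions intersect — the
conservative choice for "would this have been detected" claims. A
sequence is detectable iff a forward site and a downstream
reverse-complement reverse site co-occur on one template strand with ≤ k
mismatches each and a product length (inclusive of both primer
footprints) inside the configured range; both strands are always
examined, making detectability reverse-complement symmetric by
construction. Default k = 0 with a 0–3 option and an optional
3′-terminal-exact anchor, both off by default since the source analysis
states neither. No thermodynamic model is attempted.

## Operon synteny

Gene-order comparison against the E. coli K-12 cyoABCDE operon. Candidate
clusters chain same-scaffold genes while successive intergenic gaps stay
≤ 500 bp (configurable; no published chaining rule exists), trimmed to
the span between the first and last reference-labelled gene; minus-strand
clusters are reported in transcriptional order. Order conservation =
LCS(labels, reference) / |reference| — a gene-order score, not a sequence
alignment. Classes: identical; identical_with_insertion (≥1 unlabeled ORF
inside the full reference order, the pattern seen where an oxidoreductase
ORF rides inside the operon); partial (proper ordered subset); rearranged
(≥2 shared labels out of reference order, operationalised as
LCS < multiset overlap — with fewer than 2 shared labels the call is
partial); fragmented (reference labels split across clusters/scaffolds,
assigned at genome level — this class is this module's explicit
operationalisation of assembly fragmentation); absent.

## Synthetic community generator

The generator defines the regime every recovery test runs in:

- **Abundances**: log-normal (µ = 0, σ = 1) cell abundances across
  `n_genomes` (default 50).
- **Ultrasmall subset**: `n_ultrasmall` (default 5) genomes carry a
  planted fold-enrichment drawn log-uniformly from `enrichment_range`
  (default [100, 1000], the reported enrichment range for 0.2-µm
  filtrates).
- **Planting space**: the fold acts on *base fractions*, because the
  enrichment factor is defined on relative abundance from read mapping;
  cell fractions are derived by dividing by genome length and
  renormalising. By default the ultrasmall down-weighting factor is
  solved in closed form so concentrate base-fraction weights sum to one,
  making every realised enrichment equal its planted fold exactly; an
  explicit `rarity_factor` (e.g. 10⁻⁴) instead fixes the down-weight and
  renormalises, and the realised enrichment is recorded separately in
  the truth.
- **Filtration**: non-ultrasmall genomes persist in the concentrate at
  `concentrate_capture_of_large` (default 0 = perfect filtration).
- **Depth**: expected depth per genome d_g = p_g·S / Σ p_h·L_h, so
  Σ d_g·L_g = S (sequencing effort is conserved); per-base depths are
  independent Poisson(d_g). This reproduces the depth/breadth statistics
  the pipeline consumes (breadth → 1 − e^(−c)) without read-level
  simulation, which nothing downstream uses. Defaults
  (S_bulk = 2·10⁸, S_concentrate = 2·10⁷ over 50–150 kb genomes) put
  ultrasmall genomes around 0.1–1.6× in bulk and ~10–80× in the
  concentrate. Genome sizes are desk-scale stand-ins for Mb genomes;
  depths, not absolute sizes, drive every statistic.
- **Planting utilities**: 16S-like sequences carrying a primer pair with
  an exact number of guaranteed forward-site mismatches (each substitution
  leaves the code's IUPAC expansion); cyo operon layouts (reference /
  inserted ORF / reordered / fragmented / partial, either strand); SCG and
  metabolic hit tables realising exact completeness/contamination and
  presence truths (identifiers shared between a marker alias list and a
  pathway set are never planted, keeping the truths independent).
- Sequences, when emitted, use uniform base composition; GC realism, read
  simulation, sequencing error and chimeras are out of scope.

What passing tests show — and do not. Recovery tests demonstrate the
*estimators* are correct under the stated generative model (Poisson depth,
known bins, honest lengths). They do not exercise mapping bias, inter-bin
contamination, strain variation, or compositional effects of real soil
communities; conclusions about real data inherit the upstream mapper's and
binner's quality.

## Numerical choices

- Depth TSVs are 1-based (samtools-depth convention) and may omit
  zero-depth rows; profiles are invariant to record order and to explicit
  zero listing. Internal intervals are 0-based half-open.
- Scaffold lengths must come from FASTA or a lengths TSV — a depth file
  cannot define lengths (trailing zeros are ambiguous).
- All randomness flows through `numpy.random.default_rng` seeded from the
  spec/CLI seed; identical seeds give byte-identical outputs (manifests
  record sha256 checksums of every file).
- Degenerate inputs fail loudly: all-zero samples are flagged undefined,
  both-zero enrichment is an error, an empty concentrate is an invalid
  spec, duplicate depth positions and duplicate bin assignments are
  errors naming the offender.
- Problem sizes in tests and the acceptance script (50 genomes of
  30–60 kb, 10⁵-bp breadth checks, 200 planted 16S sequences, 20 seeds per
  operon layout) were chosen so the whole suite runs in seconds while
  keeping per-scaffold counting noise well under the tolerances asserted.

## Known limitations

- The census inherits N_total = 10⁹ cells/g wholesale; no attempt is made
  to estimate it or to correct for extraction bias.
- Contamination is set-restricted duplication, blind to contamination by
  genes outside the SCG set.
- Primer screening is purely combinatorial; melting behaviour, 3′
  extension efficiency and multi-template bias are not modelled.
- The fragmented synteny class cannot distinguish true fragmentation from
  genuinely split loci.
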