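# Methods

## Scope and model

footgrn implements the digital-genomic-footprinting route to
subtype-specific TF networks: union DHS atlas from merged cut profiles,
strand-aware binomial footprint detection, condensation of a redundant
PWM library into non-redundant TF families, promoter-capture target
linking with nearest-gene fallback, and assembly of per-subtype networks
from upregulated families, occupied motifs and linked genes. A planted-
truth generator provides the benchmark; all randomness flows from one
integer seed.

The package operates at desk scale. Cohort-scale figures quoted in the
literature for this workflow (atlases of ~128 000 DHSs from dozens of
patients at ~2×10⁸ reads each) are properties of restricted patient
data; here they inform the *structure* and *parameters* of the synthetic
benchmark (85% promoter-linked distal DHSs, 50% nearest-gene contacts,
≥3-fold TF upregulation, 400-bp windows, rank-16 000 normalization), not
reproduction targets.

## Footprint statistic

For a candidate interval of length L (default range 11–25 bp) inside a
peak window, with shoulders of S = 35 bp: the forward-strand p-value is
P[X ≥ f_sh] for X ~ Binomial(f_sh + f_fp, S/(S+L)), where f_sh counts
forward-strand cuts in [start−S, start) and f_fp in the interior. Under
a locally uniform cut rate the expected split is exactly the binomial
null, so a flat profile scores ≈ 0 regardless of depth. The reverse
strand is tested against [end, end+S). The combined score
min(−log10 p_fwd, −log10 p_rev) demands bidirectional protection — the
geometry a bound protein imposes (upstream pile-up on the forward
strand, downstream on the reverse). A strand with zero cuts in both its
shoulder and the interior is defined to score 0. Candidates scoring at
least the threshold (default 10) are accepted greedily by descending
score with deterministic tie-breaks (leftmost start, then shortest
length) and no overlap among accepted calls.

The statistic is validated against an independent brute-force binomial
tail summation (exact integer binomial coefficients) at rel. tol. 1e-9
with an absolute floor of 1e-12 for scores that are analytically ~0,
where −log10 of a tail ≈ 1 loses all relative precision in any floating-
point implementation.

Depth QC follows the observation that raw read depth predicts footprint
yield poorly: profiles are binomially thinned (nested, so lower
fractions are true subsets of higher ones; thin(p1)∘thin(p2) =
thin(p1·p2) exactly) and for each level the median peak volume (cuts in
the fixed 400-bp window) and mean footprint calls per peak are reported,
plus the smallest median volume reaching one footprint per peak.

## Atlas construction

Peak calling is deliberately the simplest deterministic caller with
stated parameters, since the upstream study does not specify one: 50-bp
bins on the merged (all samples, both strands) track, kept when
P[X ≥ count] < 1e-5 under Poisson with the genome-wide mean rate per
bin, merged across gaps ≤ 200 bp; the summit is the argmax of the 150-bp
moving-average density (ties leftmost). All four constants are exposed.

Quantification: total cuts (both strands) in [summit − 200, summit + 200)
per sample, clipped at chromosome ends. Normalization divides each
sample by its rank-r largest peak count and multiplies by a common
reference (default: across-sample median of those counts). r = 16 000
when the atlas has at least that many peaks; otherwise
r = max(1, ⌊0.125 · n_peaks⌋), preserving the 16 000/128 000 proportion.
This per-sample anchor makes the transform idempotent and exactly
invariant (under a fixed reference) to global per-sample depth changes.

Clustering: average-linkage agglomeration on 1 − Pearson correlation of
log2(1 + normalized signal) over distal peaks (distal = summit more than
2 kb from the nearest TSS; ties in nearest TSS go to the lower
coordinate). Flat groups come from cutting at k clusters with labels
canonicalized by sorted sample id, making the partition independent of
input order. Constant sample vectors are an error (correlation
undefined), not a silent drop.

Subtype-specific DHS sets use a fold-plus-presence rule (defaults:
mean signal in the subtype ≥ 2× the mean over all other samples, and
signal above a small floor in ≥ 50% of the subtype's samples). The
upstream study states no thresholding rule; this one is a declared,
configurable stand-in.

## Motif catalog

PWM similarity is the maximum over all ungapped offsets and both
orientations of the mean column-wise Pearson correlation over the
overlap, with at least 5 overlapping columns. Column conventions:
identical columns correlate 1 (so similarity(a, a) = 1 exactly, flat
columns included); otherwise a zero-variance column (no base preference)
contributes 0. Families are connected components of the similarity
graph at threshold 0.8; the representative is the member with the
highest total information content (Σ over positions of 2 + Σ p log2 p,
in bits), ties to the lexicographically first name; the family is keyed
by the representative's name for stable cross-run joins. Components
naturally separate matrices that differ substantially — the PU.1
situation within the ETS family.

Scanning: footprint call intervals ± 5 bp are scored on both strands
with the representative's log-odds matrix against genome base
frequencies (pseudocount 1e-3); a hit requires ≥ 0.8 of the PWM's
maximum achievable score (a fraction-of-max rule is exactly testable,
unlike p-value calibration), keeping the best hit per (footprint,
family). Bases outside ACGT contribute 0.

## Target linking

A distal DHS is linked to a gene when one anchor of an interaction
overlaps the DHS (≥ 1 bp) and the other overlaps the gene's promoter
(TSS ± 2 kb); anchors are unordered, duplicate (peak, gene) pairs are
collapsed with the supporting-interaction count retained. DHSs with no
such link take exactly one nearest-TSS link (ties to the lower
coordinate), so every distal DHS ends with at least one link and, with
no interaction file at all, the pipeline degrades to pure nearest-gene
assignment. Link statistics (fraction of DHSs with promoter contact,
fraction of contacts hitting the brute-force nearest gene, the same
fraction over deregulated DHSs) report None for empty denominators,
never 0.

## Network assembly

A TF gene is upregulated in subtype S when
(mean FKPM in S + 0.1)/(mean control FKPM + 0.1) ≥ 3, inclusive; the
0.1 pseudocount guards zero-control genes at the cost of shifting genes
sitting exactly at threefold slightly below threshold (a documented
boundary; pseudocount 0 restores the exact-3 inclusive behaviour).
Nodes carry all expressed members (max FKPM ≥ 1, inclusive) with
expression bins low < 3 ≤ moderate ≤ 20 < high FKPM — cutoffs invented
here, since the source figure encodes bins as colors without numbers.
An edge F → G in S requires an occupied motif of F inside a footprint
in an S-specific DHS linked to G, with F a node in S; by default
targets are restricted to TF genes (TF-to-TF networks).

Co-occupancy: the observed statistic for a family pair is the number of
same-peak occurrence pairs (distinct families) with midpoint distance
≤ 50 bp. The null permutes family labels across occurrences within each
peak — preserving per-peak occupancy density and per-family totals —
1000 times with a fixed seed; p = (1 + #{null ≥ obs})/(1 + N), BH
corrected across pairs. The upstream description names neither a null
nor a correction; both choices are recorded here as the package's own.

## Synthetic generator

What it emulates: peaks of elevated Poisson cut rate (positionwise,
both strands; enrichment 50× background) on a random genome; shared,
promoter, and subtype-private peak subsets; footprint-shaped depletions
(interior rate × 0.1) with the strand-shoulder geometry the statistic
tests (forward boost in the 35 bp upstream, reverse in the 35 bp
downstream, × 2); consensus motif instances embedded in the genome at
footprint positions; interactions covering exactly
round(0.85 · n_distal) distal peaks with exactly half the interaction
partners being the nearest gene (exact allocations, not per-peak coins,
so the planted fractions are sharp); TF expression upregulated by
fold × margin (3 × 1.5 by default — "at least threefold" — so genes sit
clearly above the detection threshold rather than exactly on the
pseudocount boundary); lognormal multiplicative noise with CV 0.2.
Edge-supporting peaks are always subtype-private and always
promoter-linked to their target; decoy footprints in private peaks are
drawn from families that are not that subtype's planted sources, so an
inferred edge is spurious if and only if it is absent from the truth.
Shared distal peaks carry two decoy instances of distinct families
48 bp apart, which puts per-sample footprint density above one per peak
and makes within-window co-localization actually present in the data.

Default cohort (the study conditions for all recovery tests): 2
chromosomes × 500 kb, 60 genes, 100 peaks (10 promoter-proximal, 25
private per subtype), 2 subtypes × 3 samples + 2 controls, 10⁶ cuts per
sample, 8 motif families × 2 TF genes, 3 planted edges per subtype.
These sizes keep a full five-seed recovery benchmark around a minute on
one CPU while leaving every stage's signal-to-noise in the regime the
method assumes (median peak volume ≫ 700).

What it does not emulate — and hence what passing tests do not show
about real data: DNase sequence-cutting bias and mappability structure,
read-level artifacts (counts are generated directly, no FASTQ/BAM),
overdispersion beyond Poisson (the cut-count distribution of real data
is not documented upstream; Poisson is this package's choice),
copy-number and clonality effects, motif instances weaker than
consensus (embedding the consensus decouples scanner calibration from
truth recovery — by design, recovery tests exercise the pipeline logic,
not PWM sensitivity), and cohort-scale class imbalance.

## Numerical and degenerate-input conventions

- All coordinates 0-based half-open; BED output native.
- Binomial tails via scipy's logsf (no underflow for the count ranges
  involved); scores of all-zero strands defined 0.
- Per-sample random streams derived as (seed, stream-tag, sample-index),
  so adding samples never perturbs existing ones; seeded runs are
  byte-identical including file checksums in the manifest.
- Rank normalization errors on a zero rank-r count (sample too shallow).
- fold = ∞ in subtype calling yields empty sets; identical signal
  everywhere yields empty sets.
- Peaks or calls referencing unknown chromosomes/peaks raise; the
  pipeline wraps stage failures with the stage name (CLI exit code 3;
  validation problems exit 2 before any compute).

## Known limitations

- The footprint statistic's constants (length range 11–25, shoulder 35,
  threshold 10) are declared defaults, not values inferred from the
  upstream study, which defers its footprinting parameterization to the
  cited method.
- The motif-hit rule (fraction-of-max 0.8) is not calibrated to a
  false-positive rate; it is chosen for exact testability.
- Co-occupancy with few occurrences per peak has a degenerate
  permutation null (two occurrences in a peak permute to themselves);
  significance requires occupancy-dense peaks.
- `summarize_catalog` can verify the published 80-family / 284-TF-gene
  catalog counts only when the corresponding supplementary table is
  supplied by the user (data/supplementary_table_s1.tsv); the table is
  not redistributed here.
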