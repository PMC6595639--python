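# footgrn

Inference of mutation-subtype-specific transcription-factor regulatory
networks from high-depth DNase I cut profiles — the digital-genomic-
footprinting workflow used to chart TF networks across AML mutation
subtypes — packaged as a tested, fully seeded Python pipeline with a
synthetic-data generator that plants a known regulatory network, so every
stage can be verified without access to restricted cohort data.

Intended for regulatory-genomics researchers who want either (a) a
desk-scale, inspectable implementation of the DHS-atlas → footprint →
motif-family → HiC-linking → network procedure, or (b) a planted-truth
benchmark for methods that claim to recover regulatory edges from
chromatin accessibility.

## The pipeline

1. **DHS atlas** — per-sample stranded 5′ cut tracks are summed and peaks
   are called once on the merged track (merging maximizes sensitivity and
   flattens background). Every sample is quantified on the same fixed
   400-bp windows around atlas summits; per-sample signal is normalized by
   the count of the peak ranked 16 000 by size (proportionally scaled for
   smaller atlases). Samples are clustered on distal peaks with
   1 − Pearson distance on log2(1+signal), average linkage; subtype-
   characteristic DHS subsets are called by fold enrichment plus presence.
2. **Digital footprints** — a bound TF protects its motif from cleavage.
   For a candidate footprint of length *L* with shoulders of *S* bp, the
   forward-strand statistic is the binomial tail

   p_fwd = P[X ≥ f_sh],  X ~ Binomial(f_sh + f_fp, S/(S+L)),

   where f_sh and f_fp are forward cuts in the upstream shoulder and in
   the interior; the reverse strand is tested symmetrically against the
   downstream shoulder, and the combined score is
   min(−log10 p_fwd, −log10 p_rev), so both strands must individually
   support the protection signature. A depth-QC curve (binomial thinning)
   reports the median peak volume needed to detect ~1 footprint per peak —
   a far better depth guide than raw read counts.
3. **Motif families** — a redundant PWM library is condensed into
   non-redundant families: pairwise similarity is the best ungapped-
   alignment mean column-wise Pearson correlation over both orientations;
   families are connected components at similarity ≥ 0.8, represented by
   the highest-information-content member and annotated with the union of
   member TF genes. Distinct matrices (the PU.1 case among ETS factors)
   keep their own family.
4. **Target linking** — each distal DHS is linked to every gene whose
   promoter its promoter-capture interactions touch; DHSs without
   promoter contacts fall back to the nearest-TSS gene. On cohort data
   ~85% of distal DHSs contact a promoter and only ~50% of those contacts
   involve the nearest gene, which is what the generator plants.
5. **Networks** — a node is a motif family with a member TF gene
   upregulated ≥ 3-fold over controls in the subtype; an edge
   family → gene requires an occupied motif of the family inside a
   subtype-specific DHS linked to that gene. Motif co-occupancy within
   50-bp windows is tested against a within-peak label-permutation null
   with BH correction.

The synthetic generator (`footgrn.simulate`) emulates exactly the
structure these stages assume and records every planted peak, footprint,
interaction and edge, so recovery is scored as plain precision/recall.

## Worked example

```sh
python examples/06_build_network.py
```

prints (seed 1, generator defaults: 2 subtypes × 3 samples + 2 controls,
100 peaks, 10⁶ cuts/sample):

```
atlas: 100 peaks; subtype-specific sets: {'S1': 25, 'S2': 25}
footprint calls: {'S1': 115, 'S2': 115}
catalog: 8 families, 16 TF genes
links: 90 (promoter-interaction fraction 0.84)
...
network edges: 6
  S2: FAM00.1 -> gene_0013 (1 supporting footprints)
  ...
recovery vs planted truth: precision=1.00 recall=1.00
```

All 100 planted DHSs are recovered in the atlas, the 25 private peaks per
subtype are correctly assigned, and all 6 planted regulatory edges are
inferred with no spurious ones. The other examples
(`examples/01…05_*.py`) walk each stage individually; a thin CLI
(`footgrn simulate`, `footgrn run --config pipeline.yaml`) wraps the
pipeline for shell use.

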