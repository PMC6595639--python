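"""Assign distal DHSs to target genes via promoter-capture interactions.

A distal DHS is linked to every gene whose promoter one of its
interactions reaches; DHSs with no promoter contact fall back to the
nearest-TSS gene.  On cohort data ~85% of distal DHSs touch at least one
promoter, and only ~50% of those contacts involve the nearest gene —
which is why nearest-gene-only assignment misleads.
"""

from footgrn import SimConfig, link_by_hic, link_stats, nearest_gene_fallback
from footgrn.atlas import Peak
from footgrn.linking import link_all
from footgrn.simulate import generate_annotation, plant_landscape

config = SimConfig(seed=1, n_peaks=250, chrom_length=1_200_000, n_genes=120)
annotation = generate_annotation(config)
truth = plant_landscape(config, annotation)
distal = truth.peaks[truth.peaks["kind"] == "distal"]
peaks = [Peak(r.chrom, r.start, r.end, r.summit, r.peak_id)
         for r in distal.itertuples()]

hic = link_by_hic(peaks, truth.interactions, annotation)
rest = [p for p in peaks if p.id not in {l.peak_id for l in hic}]
fallback = nearest_gene_fallback(rest, annotation)
print(f"distal DHSs: {len(peaks)}")
print(f"promoter-capture links: {len(hic)} (covering "
      f"{len({l.peak_id for l in hic})} DHSs)")
print(f"nearest-gene fallback links: {len(fallback)}")

stats = link_stats(link_all(peaks, truth.interactions, annotation),
                   peaks, None, annotation)
print(f"\nfraction of distal DHSs with a promoter interaction: "
      f"{stats.fraction_dhs_with_promoter_interaction:.3f} "
      f"(generator plants {config.hic_linked_fraction})")
print(f"fraction of promoter links hitting the nearest gene:  "
      f"{stats.fraction_interactions_nearest_gene:.3f} "
      f"(generator plants {config.nearest_gene_fraction})")
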