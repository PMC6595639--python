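"""Condense a redundant motif library into non-redundant TF families.

Databases assign multiple PWMs per TF and near-identical PWMs to family
members binding the same sequence.  Pairwise similarity (best ungapped
alignment over both orientations, mean column-wise Pearson correlation)
links redundant matrices; connected components become families, each
represented by its highest-information-content member and annotated with
the union of member TF genes.
"""

import numpy as np

from footgrn import PWM, condense, pwm_similarity
from footgrn.motifs import summarize_catalog


def point_mass(name, consensus):
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    mat = np.zeros((len(consensus), 4))
    for i, b in enumerate(consensus):
        mat[i, idx[b]] = 1.0
    return PWM(name, mat)


ets_like = point_mass("ETS_core", "ACCGGAAGTGAC")
shifted = PWM("ETS_shifted", np.vstack([ets_like.matrix[2:], ets_like.matrix[:2]]))
revcomp = PWM("ETS_rc", ets_like.reverse_complement().matrix)
distinct = point_mass("PU1_like", "TTATAGCCTTGG")

library = [ets_like, shifted, revcomp, distinct]
annotation = {
    "ETS_core": ["FLI1", "ERG"],
    "ETS_shifted": ["ETV6"],
    "ETS_rc": ["FLI1"],
    "PU1_like": ["SPI1"],
}

print("pairwise similarities to ETS_core:")
for p in library[1:]:
    print(f"  {p.name:<12} {pwm_similarity(ets_like, p):+.3f}")

families = condense(library, annotation, threshold=0.8)
print(f"\ncondensed into {len(families)} families:")
for f in families:
    print(f"  representative {f.family_id:<12} members: "
          f"{[p.name for p in f.member_pwms]}  TF genes: {f.member_tf_genes}")
print("  -> redundant variants of one motif collapse; the distinctive "
      "matrix keeps its own family (the PU.1 situation among ETS factors)")

n_fam, n_genes = summarize_catalog(families)
print(f"catalog summary: {n_fam} families covering {n_genes} distinct TF genes")
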