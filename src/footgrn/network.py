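"""Subtype-specific TF network assembly and motif co-occupancy.

A network node is a motif family with at least one member TF gene
upregulated (>= threshold fold over controls, with a small pseudocount)
in the subtype, carrying all other expressed members of the family.  An
edge family -> target gene requires an occupied motif of the family
inside a detected footprint lying in a subtype-specific DHS that is
linked to the target.  Co-occupancy asks which family pairs co-localize
within a short window inside the same peak more often than expected
under within-peak permutation of family labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from footgrn.linking import DHSGeneLink
from footgrn.motifs import MotifFamily, MotifOccurrence


@dataclass
class NetworkConfig:
    upregulation_fold: float = 3.0
    pseudocount: float = 0.1
    expressed_min_fkpm: float = 1.0
    bin_low_max: float = 3.0    # FKPM below this: "low"
    bin_moderate_max: float = 20.0  # up to this: "moderate"; above: "high"
    cooccupancy_window_bp: int = 50
    n_permutations: int = 1000
    fdr_alpha: float = 0.05
    targets: str = "tf_genes_only"  # or "all_genes"

    def __post_init__(self) -> None:
        if self.upregulation_fold <= 1:
            raise ValueError("upregulation_fold must exceed 1")
        if self.cooccupancy_window_bp <= 0:
            raise ValueError("cooccupancy_window_bp must be > 0")
        if self.targets not in ("tf_genes_only", "all_genes"):
            raise ValueError(f"unknown targets mode {self.targets!r}")

    def expression_bin(self, fkpm: float) -> str:
        if fkpm < self.bin_low_max:
            return "low"
        if fkpm <= self.bin_moderate_max:
            return "moderate"
        return "high"


@dataclass
class NetworkNode:
    family_id: str
    subtype: str
    upregulated_members: list[str]
    expressed_members: list[str]
    expression_bin: dict[str, str]

    def __post_init__(self) -> None:
        if not self.upregulated_members:
            raise ValueError("a node requires at least one upregulated member")
        if not set(self.upregulated_members) <= set(self.expressed_members):
            raise ValueError("upregulated members must be expressed")


@dataclass
class NetworkEdge:
    source_family: str
    target_gene: str
    subtype: str
    supporting: list[tuple[str, str, str]]  # (footprint id, peak id, link method)

    def __post_init__(self) -> None:
        if not self.supporting:
            raise ValueError("an edge requires supporting evidence")


@dataclass
class CoOccupancyResult:
    family_a: str
    family_b: str
    subtype: str
    observed: int
    null_mean: float
    p_value: float
    q_value: float


def upregulated_families(
    expression: pd.DataFrame,
    metadata: pd.DataFrame,
    families: list[MotifFamily],
    config: NetworkConfig | None = None,
    subtypes: list[str] | None = None,
) -> dict[str, list[NetworkNode]]:
    """Per-subtype network nodes from TF upregulation against controls.

    A TF gene is upregulated in subtype S iff
    ``(mean_S + c) / (mean_control + c) >= upregulation_fold`` with
    pseudocount ``c`` (inclusive threshold).  A node is emitted for every
    family with at least one upregulated member; all expressed members
    are attached with their expression bin (mean FKPM in S).
    """
    config = config or NetworkConfig()
    meta = metadata.set_index("sample_id")
    control_samples = [s for s in meta.index if meta.loc[s, "is_control"] and s in expression.columns]
    if not control_samples:
        raise ValueError("upregulation requires control samples")
    if subtypes is None:
        subtypes = sorted(meta.loc[~meta["is_control"], "subtype"].unique())

    mean_ctrl = expression[control_samples].mean(axis=1)
    c = config.pseudocount
    nodes: dict[str, list[NetworkNode]] = {}
    for s in subtypes:
        in_s = [x for x in meta.index[meta["subtype"] == s] if x in expression.columns]
        if not in_s:
            raise ValueError(f"subtype {s!r} has no expression samples")
        mean_s = expression[in_s].mean(axis=1)
        ratio = (mean_s + c) / (mean_ctrl + c)
        nodes[s] = []
        for fam in families:
            members = [g for g in fam.member_tf_genes if g in expression.index]
            expressed = [
                g for g in members
                if float(expression.loc[g, in_s].max()) >= config.expressed_min_fkpm
            ]
            up = [g for g in expressed if float(ratio.loc[g]) >= config.upregulation_fold]
            if not up:
                continue
            bins = {g: config.expression_bin(float(mean_s.loc[g])) for g in expressed}
            nodes[s].append(NetworkNode(fam.family_id, s, sorted(up), sorted(expressed), bins))
    return nodes


def build_edges(
    nodes: dict[str, list[NetworkNode]],
    occurrences: dict[str, list[MotifOccurrence]],
    dhs_sets: dict[str, list[str]],
    links: list[DHSGeneLink],
    config: NetworkConfig | None = None,
    tf_genes: set[str] | None = None,
    atlas_peak_ids: set[str] | None = None,
) -> list[NetworkEdge]:
    """Assemble edges family -> target gene per subtype.

    An edge (F -> G, subtype S) requires at least one motif occurrence of
    F (``occurrences[S]``) inside a footprint whose peak belongs to the
    S-specific DHS set and is linked to G, with F a node in S.  With
    ``targets="tf_genes_only"`` the target must be a TF gene.  Supporting
    (footprint, peak, link-method) evidence is recorded on the edge.
    """
    config = config or NetworkConfig()
    if config.targets == "tf_genes_only" and tf_genes is None:
        raise ValueError("tf_genes required when targets='tf_genes_only'")
    links_by_peak: dict[str, list[DHSGeneLink]] = {}
    for l in links:
        links_by_peak.setdefault(l.peak_id, []).append(l)

    collected: dict[tuple[str, str, str], list[tuple[str, str, str]]] = {}
    for subtype, occs in occurrences.items():
        node_families = {n.family_id for n in nodes.get(subtype, [])}
        specific = set(dhs_sets.get(subtype, []))
        for occ in occs:
            if atlas_peak_ids is not None and occ.peak_id not in atlas_peak_ids:
                raise ValueError(f"occurrence references unknown peak {occ.peak_id!r}")
            if occ.family_id not in node_families or occ.peak_id not in specific:
                continue
            for link in links_by_peak.get(occ.peak_id, []):
                if config.targets == "tf_genes_only" and link.gene_id not in tf_genes:
                    continue
                key = (occ.family_id, link.gene_id, subtype)
                collected.setdefault(key, []).append((occ.call_id, occ.peak_id, link.method))

    edges = [
        NetworkEdge(fam, gene, subtype, sorted(set(sup)))
        for (fam, gene, subtype), sup in sorted(collected.items())
    ]
    return edges


def co_occupancy(
    occurrences: list[MotifOccurrence],
    config: NetworkConfig | None = None,
    seed: int = 0,
    subtype: str = "",
) -> list[CoOccupancyResult]:
    """Within-peak motif co-localization with a permutation null.

    The observed count for a family pair is the number of occurrence
    pairs (distinct families) in the same peak whose midpoints lie
    within ``cooccupancy_window_bp``.  The null permutes family labels
    across occurrences within each peak, preserving per-family totals;
    the empirical p-value is ``(1 + #{null >= observed}) / (1 + n)``,
    BH-corrected across pairs.
    """
    config = config or NetworkConfig()
    if config.n_permutations < 100:
        warnings.warn("fewer than 100 permutations gives a coarse null")

    by_peak: dict[str, list[MotifOccurrence]] = {}
    for occ in occurrences:
        by_peak.setdefault(occ.peak_id, []).append(occ)
    # deterministic order regardless of input order
    peaks = {
        pk: sorted(v, key=lambda o: (o.start, o.end, o.family_id))
        for pk, v in sorted(by_peak.items())
    }

    def count_pairs(labels_by_peak):
        counts: dict[tuple[str, str], int] = {}
        for pk, occs in peaks.items():
            labels = labels_by_peak[pk]
            mids = [(o.start + o.end) / 2 for o in occs]
            for i in range(len(occs)):
                for j in range(i + 1, len(occs)):
                    if labels[i] == labels[j]:
                        continue
                    if abs(mids[i] - mids[j]) <= config.cooccupancy_window_bp:
                        pair = tuple(sorted((labels[i], labels[j])))
                        counts[pair] = counts.get(pair, 0) + 1
        return counts

    base_labels = {pk: [o.family_id for o in occs] for pk, occs in peaks.items()}
    observed = count_pairs(base_labels)

    families = sorted({o.family_id for o in occurrences})
    if len(families) < 2:
        raise ValueError("co-occupancy requires occurrences from at least 2 families")
    candidate_pairs = sorted(observed)
    if not candidate_pairs:
        return []

    rng = np.random.default_rng(seed)
    exceed = {pair: 0 for pair in candidate_pairs}
    null_sum = {pair: 0.0 for pair in candidate_pairs}
    for _ in range(config.n_permutations):
        perm_labels = {
            pk: [labels[i] for i in rng.permutation(len(labels))]
            for pk, labels in base_labels.items()
        }
        null_counts = count_pairs(perm_labels)
        for pair in candidate_pairs:
            c = null_counts.get(pair, 0)
            null_sum[pair] += c
            if c >= observed[pair]:
                exceed[pair] += 1

    n = config.n_permutations
    pvals = [(1 + exceed[p]) / (1 + n) for p in candidate_pairs]
    qvals = multipletests(pvals, method="fdr_bh")[1] if pvals else []
    return [
        CoOccupancyResult(pair[0], pair[1], subtype, observed[pair],
                          null_sum[pair] / n, pv, float(qv))
        for pair, pv, qv in zip(candidate_pairs, pvals, qvals)
    ]


def to_graph(nodes: dict[str, list[NetworkNode]], edges: list[NetworkEdge]) -> nx.DiGraph:
    """Directed graph with one node per (subtype, family) and per target gene."""
    g = nx.DiGraph()
    node_ids = set()
    for subtype in sorted(nodes):
        for node in sorted(nodes[subtype], key=lambda n: n.family_id):
            nid = f"{subtype}:{node.family_id}"
            node_ids.add((subtype, node.family_id))
            g.add_node(
                nid,
                kind="family",
                subtype=subtype,
                family_id=node.family_id,
                upregulated_members=";".join(node.upregulated_members),
                expressed_members=";".join(node.expressed_members),
                expression_bins=";".join(
                    f"{m}={node.expression_bin[m]}" for m in node.expressed_members
                ),
            )
    for e in sorted(edges, key=lambda e: (e.subtype, e.source_family, e.target_gene)):
        if (e.subtype, e.source_family) not in node_ids:
            raise ValueError(
                f"dangling edge: {e.source_family} is not a node in {e.subtype}"
            )
        tid = f"{e.subtype}:{e.target_gene}"
        if tid not in g:
            g.add_node(tid, kind="gene", subtype=e.subtype, gene_id=e.target_gene)
        g.add_edge(
            f"{e.subtype}:{e.source_family}", tid,
            subtype=e.subtype,
            n_supporting=len(e.supporting),
            supporting=";".join(",".join(s) for s in e.supporting),
        )
    return g


def export_network(
    nodes: dict[str, list[NetworkNode]],
    edges: list[NetworkEdge],
    graphml_path,
    edge_tsv_path,
) -> nx.DiGraph:
    """Write the network as GraphML plus a TSV edge list; returns the graph.

    Reading the GraphML back yields a graph equal (nodes, edges,
    attributes) to the written one.
    """
    g = to_graph(nodes, edges)
    nx.write_graphml(g, graphml_path)
    rows = [
        {
            "subtype": e.subtype,
            "source_family": e.source_family,
            "target_gene": e.target_gene,
            "n_supporting": len(e.supporting),
            "supporting": ";".join(",".join(s) for s in e.supporting),
        }
        for e in sorted(edges, key=lambda e: (e.subtype, e.source_family, e.target_gene))
    ]
    pd.DataFrame(rows, columns=["subtype", "source_family", "target_gene",
                                "n_supporting", "supporting"]).to_csv(
        edge_tsv_path, sep="\t", index=False
    )
    return g


def score_edge_recovery(
    edges: list[NetworkEdge],
    truth,
    family_of: callable = None,
) -> tuple[float, float]:
    """(precision, recall) of inferred edges against planted truth.

    Catalog family ids are representative PWM names; ``family_of`` maps
    them onto planted family labels (default: strip the member suffix,
    e.g. ``FAM03.2 -> FAM03``).
    """
    if family_of is None:
        family_of = lambda fid: fid.split(".")[0]
    predicted = {(family_of(e.source_family), e.target_gene, e.subtype) for e in edges}
    true = {
        (t.family_id, t.target_gene, t.subtype) for t in truth.edges.itertuples()
    }
    if not predicted:
        return (1.0 if not true else 0.0), (1.0 if not true else 0.0)
    tp = len(predicted & true)
    precision = tp / len(predicted)
    recall = tp / len(true) if true else 1.0
    return precision, recall
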