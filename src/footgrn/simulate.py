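"""Synthetic cohorts with a planted regulatory network.

The generator emulates the statistical structure the pipeline assumes:
open-chromatin peaks with elevated DNase cut density, footprint-shaped
strand-imbalanced cut depletions at planted motif instances,
subtype-private peak subsets, upregulated TF genes per subtype, and a
promoter-capture interaction file in which a configurable fraction of
distal peaks contacts a promoter.  Every planted event is recorded in a
:class:`PlantedTruth` so recovery can be scored exactly.

Cut counts are drawn positionwise from a Poisson whose rate landscape is
flat background, elevated inside peaks active in the sample's subtype,
multiplied by ``footprint_depletion`` inside planted footprints, and
boosted on the forward strand immediately upstream and on the reverse
strand immediately downstream of each footprint (the strand shoulder
geometry a footprint statistic tests).  The whole landscape is rescaled
so the expected total equals the requested depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from footgrn.motifs import BASES, PWM

CONTROL_LABEL = "control"
SHARED_LABEL = "shared"


class ConfigError(ValueError):
    """Raised when a simulation configuration cannot be realized."""


@dataclass
class SimConfig:
    """Generative parameters of a synthetic cohort.

    Fractions mirror the observed cohort statistics the pipeline is built
    around: 85% of distal DHSs contacting at least one promoter, 50% of
    interactions landing on the nearest gene, TF upregulation of at least
    threefold in the owning subtype, and 400-bp peak quantification
    windows.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 500_000
    n_genes: int = 60
    n_peaks: int = 100
    n_subtypes: int = 2
    samples_per_subtype: int = 3
    n_control_samples: int = 2
    reads_per_sample: int = 1_000_000
    peak_width: int = 400
    footprint_depletion: float = 0.1
    background_rate: float = 1.0
    peak_enrichment: float = 50.0
    subtype_specific_fraction: float = 0.25
    promoter_peak_fraction: float = 0.1
    hic_linked_fraction: float = 0.85
    nearest_gene_fraction: float = 0.5
    tf_upregulation_fold: float = 3.0
    planted_fold_margin: float = 1.5
    expression_noise_cv: float = 0.2
    n_motif_families: int = 8
    tf_genes_per_family: int = 2
    n_edges_per_subtype: int = 3
    base_fkpm: float = 2.0
    motif_length: int = 12
    footprint_shoulder_boost: float = 2.0
    shoulder_bp: int = 35
    decoy_footprint_prob: float = 1.0
    promoter_margin_bp: int = 2000

    def __post_init__(self) -> None:
        fractions = {
            "footprint_depletion": self.footprint_depletion,
            "subtype_specific_fraction": self.subtype_specific_fraction,
            "promoter_peak_fraction": self.promoter_peak_fraction,
            "hic_linked_fraction": self.hic_linked_fraction,
            "nearest_gene_fraction": self.nearest_gene_fraction,
            "decoy_footprint_prob": self.decoy_footprint_prob,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        if self.n_peaks * self.peak_width >= self.n_chromosomes * self.chrom_length:
            raise ConfigError("peaks do not fit on the genome")
        if self.n_edges_per_subtype * self.n_subtypes > self.n_motif_families:
            raise ConfigError("not enough motif families for disjoint per-subtype sources")
        if self.tf_upregulation_fold <= 1.0:
            raise ConfigError("tf_upregulation_fold must exceed 1")

    @property
    def subtypes(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_subtypes)]


@dataclass
class Annotation:
    """Synthetic genome and gene annotation (coordinates 0-based half-open)."""

    genome: dict[str, np.ndarray]  # chrom -> uint8 ASCII bases, mutable
    genes: pd.DataFrame  # gene_id, chrom, tss, strand, start, end

    def sequences(self) -> dict[str, str]:
        return {c: arr.tobytes().decode("ascii") for c, arr in self.genome.items()}


@dataclass
class PlantedTruth:
    """Exact record of every planted regulatory event."""

    config: SimConfig
    annotation: Annotation
    peaks: pd.DataFrame        # peak_id, chrom, start, end, summit, kind, subtype
    footprints: pd.DataFrame   # peak_id, chrom, start, end, family_id, strand
    edges: pd.DataFrame        # family_id, target_gene, subtype, peak_id
    links: pd.DataFrame        # peak_id, gene_id, via (hic|nearest)
    interactions: pd.DataFrame  # chrom1, start1, end1, chrom2, start2, end2, name
    families: dict[str, dict]  # family_id -> {"genes": [...], "consensus": str}
    pwms: list[PWM]            # full redundant library
    tf_annotation: dict[str, list[str]]  # pwm name -> TF genes
    upregulated: dict[str, list[str]]    # subtype -> upregulated TF genes
    source_families: dict[str, list[str]]  # subtype -> planted source families

    def validate(self) -> None:
        """Check the structural invariants of the planted landscape."""
        peaks = self.peaks.set_index("peak_id")
        for fp in self.footprints.itertuples():
            p = peaks.loc[fp.peak_id]
            assert p.start <= fp.start and fp.end <= p.end, "footprint escapes its peak"
        linked = {(l.peak_id, l.gene_id) for l in self.links.itertuples()}
        fp_by_peak = self.footprints.groupby("peak_id")["family_id"].apply(set)
        for e in self.edges.itertuples():
            assert (e.peak_id, e.target_gene) in linked, "edge peak not linked to target"
            assert e.family_id in fp_by_peak.get(e.peak_id, set()), "edge lacks footprint"


@dataclass
class StrandedCutProfile:
    """Per-base 5' DNase cut counts on each strand for one sample."""

    sample_id: str
    fwd: dict[str, np.ndarray]
    rev: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for strand in (self.fwd, self.rev):
            for chrom, arr in strand.items():
                if (arr < 0).any():
                    raise ValueError(f"negative cut counts on {chrom}")

    @property
    def chroms(self) -> list[str]:
        return sorted(self.fwd)

    def total_cuts(self) -> int:
        return int(sum(a.sum() for a in self.fwd.values())
                   + sum(a.sum() for a in self.rev.values()))

    def merged_track(self) -> dict[str, np.ndarray]:
        """Both strands summed, per chromosome."""
        return {c: self.fwd[c] + self.rev[c] for c in self.fwd}

    def add(self, other: "StrandedCutProfile", sample_id: str | None = None) -> "StrandedCutProfile":
        if set(self.fwd) != set(other.fwd):
            raise ValueError("profiles cover different chromosomes")
        sid = sample_id or f"{self.sample_id}+{other.sample_id}"
        return StrandedCutProfile(
            sid,
            {c: self.fwd[c] + other.fwd[c] for c in self.fwd},
            {c: self.rev[c] + other.rev[c] for c in self.rev},
        )

    def thin(self, fraction: float, seed) -> "StrandedCutProfile":
        """Binomial thinning: each cut kept independently with ``fraction``."""
        if not 0.0 <= fraction <= 1.0:
            raise ValueError("thinning fraction must be in [0, 1]")
        if fraction == 1.0:
            return StrandedCutProfile(
                self.sample_id,
                {c: a.copy() for c, a in self.fwd.items()},
                {c: a.copy() for c, a in self.rev.items()},
            )
        rng = np.random.default_rng(seed)
        return StrandedCutProfile(
            self.sample_id,
            {c: rng.binomial(a, fraction) for c, a in sorted(self.fwd.items())},
            {c: rng.binomial(a, fraction) for c, a in sorted(self.rev.items())},
        )


def merge_profiles(profiles: list[StrandedCutProfile], sample_id: str = "merged") -> StrandedCutProfile:
    if not profiles:
        raise ValueError("no profiles to merge")
    out = profiles[0]
    for p in profiles[1:]:
        out = out.add(p)
    return StrandedCutProfile(sample_id, out.fwd, out.rev)


def _chrom_names(config: SimConfig) -> list[str]:
    return [f"chr{i + 1}" for i in range(config.n_chromosomes)]


def generate_annotation(config: SimConfig) -> Annotation:
    """Random genome plus non-overlapping genes with distinct TSS.

    Gene bodies are 1 kb downstream of the TSS along the gene's strand.
    Motif instances are embedded into the genome later, when the
    regulatory landscape is planted (:func:`plant_landscape`).
    """
    rng = np.random.default_rng([config.seed, 1])
    chroms = _chrom_names(config)
    genome = {
        c: rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=config.chrom_length)
        for c in chroms
    }

    gene_body = 1000
    margin = 5000
    spacing = 6000  # keeps TSS and bodies apart and leaves room for distal peaks
    rows = []
    if config.n_genes > 0:
        per_chrom = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
        per_chrom[: config.n_genes % config.n_chromosomes] += 1
        gi = 0
        for c, n_here in zip(chroms, per_chrom):
            usable = config.chrom_length - 2 * margin
            if n_here > 0 and usable < (n_here - 1) * spacing + 1:
                raise ConfigError("genes do not fit on genome at required spacing")
            if n_here == 0:
                continue
            slot = usable // n_here
            starts = margin + np.arange(n_here) * slot
            jitter = rng.integers(0, max(1, slot - spacing // 2), size=n_here)
            for s, j in zip(starts, jitter):
                tss = int(s + j)
                strand = "+" if rng.random() < 0.5 else "-"
                start, end = (tss, tss + gene_body) if strand == "+" else (tss - gene_body + 1, tss + 1)
                rows.append((f"gene_{gi:04d}", c, tss, strand, max(0, start),
                             min(config.chrom_length, end)))
                gi += 1
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand", "start", "end"])
    return Annotation(genome=genome, genes=genes)


def _make_family_pwms(config: SimConfig, rng: np.random.Generator, tf_gene_pool: list[str]):
    """Point-mass-like family representatives with dissimilar consensi,
    plus redundant members (reverse-complemented and shifted variants).

    ``tf_gene_pool`` supplies annotation gene ids to serve as the member
    TF genes, ``tf_genes_per_family`` consecutive ids per family.
    """
    from footgrn.motifs import pwm_similarity

    L = config.motif_length
    uniform_col = np.full((1, 4), 0.25)

    def make_members(fam: str, mat: np.ndarray) -> list[PWM]:
        rep = PWM(f"{fam}.1", mat, source="synthetic")
        rc = rep.reverse_complement()
        return [
            rep,
            PWM(f"{fam}.2", rc.matrix, source="synthetic"),
            PWM(f"{fam}.3", np.vstack([mat[1:], uniform_col]), source="synthetic"),
        ]

    # Rejection-sample consensi so that every member variant of a family
    # stays clearly below the condensation threshold against every member
    # of every other family; otherwise chance k-mer overlaps could merge
    # two planted families and recovery scoring would be ill-posed.
    accepted_members: list[list[PWM]] = []
    consensi: list[str] = []
    attempts = 0
    while len(accepted_members) < config.n_motif_families:
        attempts += 1
        if attempts > 2000:
            raise ConfigError("could not sample dissimilar motif consensi")
        idx = rng.integers(0, 4, size=L)
        mat = np.full((L, 4), 0.01)
        mat[np.arange(L), idx] = 0.97
        cand = make_members(f"FAM{len(accepted_members):02d}", mat)
        if all(
            pwm_similarity(c, m) < 0.7
            for members in accepted_members for m in members for c in cand
        ):
            accepted_members.append(cand)
            consensi.append("".join(BASES[i] for i in idx))

    pwms: list[PWM] = []
    tf_annotation: dict[str, list[str]] = {}
    families: dict[str, dict] = {}
    for fi, members in enumerate(accepted_members):
        fam = f"FAM{fi:02d}"
        genes = tf_gene_pool[
            fi * config.tf_genes_per_family:(fi + 1) * config.tf_genes_per_family
        ]
        pwms.extend(members)
        tf_annotation[members[0].name] = list(genes)
        tf_annotation[members[1].name] = genes[:1]
        tf_annotation[members[2].name] = genes[-1:]
        families[fam] = {"genes": genes, "consensus": consensi[fi],
                         "representative": members[0].name}
    return pwms, tf_annotation, families


def _place_peaks(config: SimConfig, annotation: Annotation, rng: np.random.Generator):
    """Non-overlapping summit positions: promoter peaks near a TSS, distal
    peaks beyond the promoter margin from every TSS."""
    n_prom = int(round(config.promoter_peak_fraction * config.n_peaks))
    n_distal = config.n_peaks - n_prom
    half = config.peak_width // 2
    guard = config.promoter_margin_bp + half + 100
    min_gap = config.peak_width + 600  # keeps called peaks from merging

    tss_by_chrom = {
        c: np.sort(g["tss"].to_numpy())
        for c, g in annotation.genes.groupby("chrom")
    }
    chroms = _chrom_names(config)

    placed: dict[str, list[int]] = {c: [] for c in chroms}

    def far_enough(c: str, pos: int) -> bool:
        return all(abs(pos - q) >= min_gap for q in placed[c])

    rows = []
    # promoter peaks: summit within 300 bp of a TSS, distinct genes
    if n_prom > 0:
        if len(annotation.genes) == 0:
            raise ConfigError("promoter peaks requested but no genes")
        gidx = rng.permutation(len(annotation.genes))[:n_prom]
        if len(gidx) < n_prom:
            raise ConfigError("not enough genes for promoter peaks")
        for k, i in enumerate(gidx):
            g = annotation.genes.iloc[i]
            summit = int(g.tss + rng.integers(-300, 301))
            summit = int(np.clip(summit, half, config.chrom_length - half - 1))
            if not far_enough(g.chrom, summit):
                continue
            placed[g.chrom].append(summit)
            rows.append((g.chrom, summit, "promoter"))
    # distal peaks: uniform, rejected near TSS or existing peaks
    attempts = 0
    while sum(1 for r in rows if r[2] == "distal") < n_distal:
        attempts += 1
        if attempts > 200 * config.n_peaks:
            raise ConfigError("could not place distal peaks; genome too crowded")
        c = chroms[int(rng.integers(0, len(chroms)))]
        summit = int(rng.integers(half + 50, config.chrom_length - half - 50))
        tss = tss_by_chrom.get(c, np.empty(0))
        if tss.size and np.min(np.abs(tss - summit)) <= guard:
            continue
        if not far_enough(c, summit):
            continue
        placed[c].append(summit)
        rows.append((c, summit, "distal"))

    rows.sort(key=lambda r: (r[0], r[1]))
    peaks = pd.DataFrame(rows, columns=["chrom", "summit", "kind"])
    peaks["start"] = peaks["summit"] - half
    peaks["end"] = peaks["summit"] + half
    peaks["peak_id"] = [f"tpk_{i:04d}" for i in range(len(peaks))]
    return peaks[["peak_id", "chrom", "start", "end", "summit", "kind"]]


def _nearest_gene(genes: pd.DataFrame, chrom: str, pos: int) -> str | None:
    """Gene with the TSS closest to ``pos``; ties to the lower coordinate."""
    sub = genes[genes["chrom"] == chrom]
    if not len(sub):
        return None
    d = (sub["tss"] - pos).abs()
    best = d.min()
    cands = sub[d == best].sort_values("tss")
    return str(cands.iloc[0]["gene_id"])


def plant_landscape(config: SimConfig, annotation: Annotation) -> PlantedTruth:
    """Plant peaks, footprints, interactions and a regulatory network.

    Peaks are partitioned into shared and per-subtype-private sets.  Each
    planted edge (source family -> target TF gene, subtype) is realized
    as a consensus motif instance centered in a subtype-private distal
    peak that is linked to the target's promoter by a promoter-capture
    interaction.  ``hic_linked_fraction`` of distal peaks receive an
    interaction overall; interaction partners are the nearest gene with
    probability ``nearest_gene_fraction``, otherwise a random other gene.
    Consensus sequences are embedded into the genotype at footprint
    positions so motif scanning recovers them exactly.
    """
    rng = np.random.default_rng([config.seed, 2])
    n_tf = config.n_motif_families * config.tf_genes_per_family
    if n_tf > len(annotation.genes):
        raise ConfigError("not enough genes to serve as TF genes")
    tf_gene_pool = sorted(
        annotation.genes["gene_id"].iloc[rng.permutation(len(annotation.genes))[:n_tf]]
    )
    pwms, tf_annotation, families = _make_family_pwms(config, rng, tf_gene_pool)
    family_ids = sorted(families)

    peaks = _place_peaks(config, annotation, rng)
    distal_idx = peaks.index[peaks["kind"] == "distal"].to_numpy()
    n_distal = distal_idx.size

    n_private_each = int(round(config.subtype_specific_fraction * config.n_peaks))
    if n_private_each * config.n_subtypes > n_distal:
        raise ConfigError("requested private peaks exceed available distal peaks")

    subtype_of = pd.Series(SHARED_LABEL, index=peaks.index)
    shuffled = rng.permutation(distal_idx)
    private: dict[str, np.ndarray] = {}
    for i, s in enumerate(config.subtypes):
        sel = shuffled[i * n_private_each:(i + 1) * n_private_each]
        private[s] = sel
        subtype_of.loc[sel] = s
    peaks = peaks.assign(subtype=subtype_of)

    # planted edges: one per source family per subtype, disjoint sources
    fam_order = [family_ids[i] for i in rng.permutation(len(family_ids))]
    source_families = {
        s: sorted(fam_order[i * config.n_edges_per_subtype:(i + 1) * config.n_edges_per_subtype])
        for i, s in enumerate(config.subtypes)
    }
    genes = annotation.genes
    tf_genes_all = sorted({g for fam in families.values() for g in fam["genes"]})
    edge_rows = []
    edge_peak_of: dict[int, tuple[str, str]] = {}  # peak index -> (family, target)
    for s in config.subtypes:
        if len(private[s]) < len(source_families[s]):
            raise ConfigError("not enough private peaks to host planted edges")
        host_peaks = rng.permutation(private[s])[: len(source_families[s])]
        for fam, pidx in zip(source_families[s], host_peaks):
            fam_genes = set(families[fam]["genes"])
            candidates = [g for g in tf_genes_all if g not in fam_genes]
            target = candidates[int(rng.integers(0, len(candidates)))]
            edge_rows.append((fam, target, s, peaks.loc[pidx, "peak_id"]))
            edge_peak_of[int(pidx)] = (fam, target)
    edges = pd.DataFrame(edge_rows, columns=["family_id", "target_gene", "subtype", "peak_id"])

    # footprints: every edge peak gets its source-family instance; other
    # peaks get decoy instances from families that cannot fake an edge.
    # Shared distal peaks carry two decoys 48 bp apart (distinct families)
    # so that per-sample footprint density exceeds one per peak and motif
    # co-localization within 50 bp actually occurs in the data.
    fp_rows = []
    half_m = config.motif_length // 2
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

    def plant_instance(p, fam, center):
        start = int(center) - half_m
        end = start + config.motif_length
        strand = "+" if rng.random() < 0.5 else "-"
        consensus = families[fam]["consensus"]
        if strand == "-":
            consensus = "".join(comp[b] for b in reversed(consensus))
        annotation.genome[p.chrom][start:end] = np.frombuffer(
            consensus.encode("ascii"), dtype=np.uint8
        )
        fp_rows.append((p.peak_id, p.chrom, start, end, fam, strand))

    for pidx in peaks.index:
        p = peaks.loc[pidx]
        if int(pidx) in edge_peak_of:
            plant_instance(p, edge_peak_of[int(pidx)][0], p.summit)
            continue
        if rng.random() >= config.decoy_footprint_prob:
            continue
        if p.subtype in source_families:
            allowed = [f for f in family_ids if f not in source_families[p.subtype]]
        else:
            allowed = list(family_ids)
        if not allowed:
            continue
        if p.subtype == SHARED_LABEL and p.kind == "distal" and len(allowed) >= 2:
            pair = [allowed[i] for i in rng.choice(len(allowed), size=2, replace=False)]
            plant_instance(p, pair[0], p.summit - 24)
            plant_instance(p, pair[1], p.summit + 24)
        else:
            plant_instance(p, allowed[int(rng.integers(0, len(allowed)))], p.summit)
    footprints = pd.DataFrame(
        fp_rows, columns=["peak_id", "chrom", "start", "end", "family_id", "strand"]
    )

    # promoter-capture interactions over distal peaks
    n_linked = int(round(config.hic_linked_fraction * n_distal))
    edge_pidx = sorted(edge_peak_of)
    other_distal = np.array([i for i in distal_idx if i not in edge_peak_of])
    n_more = max(0, n_linked - len(edge_pidx))
    extra = rng.permutation(other_distal)[:n_more]
    linked_idx = sorted(set(edge_pidx) | set(int(i) for i in extra))

    # exactly nearest_gene_fraction of interactions target the nearest gene
    # (edge-peak interactions target the planted edge gene and count as
    # non-nearest); realized as an exact allocation, not a per-peak coin
    non_edge_linked = [i for i in linked_idx if i not in edge_peak_of]
    n_nearest = min(len(non_edge_linked),
                    int(round(config.nearest_gene_fraction * len(linked_idx))))
    nearest_set = {
        non_edge_linked[i]
        for i in rng.permutation(len(non_edge_linked))[:n_nearest]
    }

    gene_lookup = genes.set_index("gene_id")
    inter_rows, link_rows = [], []
    for pidx in linked_idx:
        p = peaks.loc[pidx]
        if int(pidx) in edge_peak_of:
            partner = edge_peak_of[int(pidx)][1]
        else:
            nearest = _nearest_gene(genes, p.chrom, int(p.summit))
            if nearest is None:
                continue
            if pidx in nearest_set:
                partner = nearest
            else:
                others = [g for g in genes["gene_id"] if g != nearest]
                partner = others[int(rng.integers(0, len(others)))] if others else nearest
        g = gene_lookup.loc[partner]
        inter_rows.append((p.chrom, int(p.start), int(p.end),
                           g.chrom, int(g.tss) - 500, int(g.tss) + 500,
                           f"{p.peak_id}--{partner}"))
        link_rows.append((p.peak_id, partner, "hic"))
    for pidx in distal_idx:
        if int(pidx) in set(linked_idx):
            continue
        p = peaks.loc[pidx]
        nearest = _nearest_gene(genes, p.chrom, int(p.summit))
        if nearest is not None:
            link_rows.append((p.peak_id, nearest, "nearest"))

    interactions = pd.DataFrame(
        inter_rows,
        columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2", "name"],
    )
    links = pd.DataFrame(link_rows, columns=["peak_id", "gene_id", "via"])

    upregulated = {
        s: sorted({g for fam in source_families[s] for g in families[fam]["genes"]})
        for s in config.subtypes
    }

    return PlantedTruth(
        config=config,
        annotation=annotation,
        peaks=peaks.reset_index(drop=True),
        footprints=footprints,
        edges=edges,
        links=links,
        interactions=interactions,
        families=families,
        pwms=pwms,
        tf_annotation=tf_annotation,
        upregulated=upregulated,
        source_families=source_families,
    )


def _active_kinds(truth: PlantedTruth, subtype: str) -> pd.Series:
    config = truth.config
    if subtype != CONTROL_LABEL and subtype not in config.subtypes:
        raise ValueError(f"unknown subtype label {subtype!r}")
    peaks = truth.peaks
    active = (peaks["subtype"] == SHARED_LABEL) | (peaks["kind"] == "promoter")
    if subtype != CONTROL_LABEL:
        active |= peaks["subtype"] == subtype
    return active


def simulate_cuts(
    truth: PlantedTruth,
    sample_id: str,
    subtype: str,
    depth: int,
    seed,
) -> StrandedCutProfile:
    """Draw a stranded cut profile for one sample of the given subtype.

    ``subtype`` may be a planted subtype label or ``"control"`` (shared
    and promoter peaks only).  The expected total over both strands
    equals ``depth``.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    config = truth.config
    active = _active_kinds(truth, subtype)
    chroms = _chrom_names(config)

    half_bg = config.background_rate / 2.0
    rate_f = {c: np.full(config.chrom_length, half_bg) for c in chroms}
    rate_r = {c: np.full(config.chrom_length, half_bg) for c in chroms}
    peak_rate = half_bg * config.peak_enrichment
    active_peak_ids = set()
    for p in truth.peaks[active].itertuples():
        rate_f[p.chrom][p.start:p.end] = peak_rate
        rate_r[p.chrom][p.start:p.end] = peak_rate
        active_peak_ids.add(p.peak_id)

    S = config.shoulder_bp
    boost = config.footprint_shoulder_boost
    for fp in truth.footprints.itertuples():
        if fp.peak_id not in active_peak_ids:
            continue
        rate_f[fp.chrom][fp.start:fp.end] *= config.footprint_depletion
        rate_r[fp.chrom][fp.start:fp.end] *= config.footprint_depletion
        rate_f[fp.chrom][max(0, fp.start - S):fp.start] *= boost
        rate_r[fp.chrom][fp.end:fp.end + S] *= boost

    total = sum(a.sum() for a in rate_f.values()) + sum(a.sum() for a in rate_r.values())
    factor = depth / total if total > 0 else 0.0
    rng = np.random.default_rng(seed)
    fwd = {c: rng.poisson(rate_f[c] * factor) for c in chroms}
    rev = {c: rng.poisson(rate_r[c] * factor) for c in chroms}
    return StrandedCutProfile(sample_id, fwd, rev)


def simulate_expression(
    truth: PlantedTruth,
    config: SimConfig,
    samples: pd.DataFrame,
) -> pd.DataFrame:
    """FKPM table (genes x samples) with planted subtype TF upregulation.

    Every gene gets a per-gene baseline around ``base_fkpm``; member TF
    genes of a subtype's source families are multiplied by
    ``tf_upregulation_fold x planted_fold_margin`` in that subtype's
    samples (so the change is at least the threshold fold).  Multiplicative
    lognormal noise with coefficient of variation ``expression_noise_cv``
    is applied per measurement; with cv=0 values are exact.
    """
    genes = list(truth.annotation.genes["gene_id"])
    if samples is None or len(samples) == 0:
        return pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    rng_gene = np.random.default_rng([config.seed, 101])
    baseline = config.base_fkpm * 2.0 ** rng_gene.uniform(-2, 2, size=len(genes))
    baseline = pd.Series(baseline, index=genes)

    fold = config.tf_upregulation_fold * config.planted_fold_margin
    cv = config.expression_noise_cv
    sigma = float(np.sqrt(np.log1p(cv * cv)))

    cols = {}
    for k, row in enumerate(samples.itertuples()):
        values = baseline.copy()
        up = truth.upregulated.get(row.subtype, [])
        values.loc[values.index.isin(up)] *= fold
        if cv > 0:
            rng_s = np.random.default_rng([config.seed, 201, k])
            noise = rng_s.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=len(values))
            values = values * noise
        cols[row.sample_id] = values
    out = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    return out


def cohort_metadata(config: SimConfig) -> pd.DataFrame:
    """Sample sheet: one row per sample with subtype label and control flag."""
    rows = []
    for s in config.subtypes:
        for j in range(config.samples_per_subtype):
            rows.append((f"{s}_rep{j + 1}", s, False))
    for j in range(config.n_control_samples):
        rows.append((f"{CONTROL_LABEL}_rep{j + 1}", CONTROL_LABEL, True))
    return pd.DataFrame(rows, columns=["sample_id", "subtype", "is_control"])


def simulate_cohort(config: SimConfig) -> dict:
    """Full synthetic cohort: annotation, truth, profiles, expression, metadata.

    Per-sample random streams are derived from the global seed and the
    sample's index, so adding samples never perturbs existing ones.
    """
    annotation = generate_annotation(config)
    truth = plant_landscape(config, annotation)
    metadata = cohort_metadata(config)
    profiles = [
        simulate_cuts(truth, row.sample_id, row.subtype, config.reads_per_sample,
                      seed=[config.seed, 301, k])
        for k, row in enumerate(metadata.itertuples())
    ]
    expression = simulate_expression(truth, config, metadata)
    return {
        "config": config,
        "annotation": annotation,
        "truth": truth,
        "metadata": metadata,
        "profiles": profiles,
        "expression": expression,
    }
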