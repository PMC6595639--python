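"""Non-redundant motif catalog: PWM similarity, family condensation, scanning.

Different databases routinely assign multiple position weight matrices
(PWMs) to the same transcription factor, and near-identical PWMs to
different members of a TF family that bind the same sequence.  Network
inference over such a redundant library would multiply-count the same
binding signal.  The catalog step condenses the library into families,
each a connected component of pairwise-similar PWMs represented by a
single matrix and annotated with the union of member TF genes; TFs whose
matrices differ substantially (the classic example being PU.1 among the
ETS factors) fall out of the component and keep their own family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
UNIFORM_BG = np.full(4, 0.25)


@dataclass
class PWM:
    """A position weight matrix: per-position base probabilities.

    ``matrix`` has shape (length, 4) with base order A, C, G, T; each
    position (row) sums to 1.
    """

    name: str
    matrix: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"PWM {self.name!r}: matrix must be (L, 4)")
        if self.matrix.shape[0] < 4:
            raise ValueError(f"PWM {self.name!r}: length must be >= 4")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.name!r}: positions must sum to 1")
        if (self.matrix < 0).any():
            raise ValueError(f"PWM {self.name!r}: negative probabilities")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_counts(cls, name: str, counts: np.ndarray, source: str = "") -> "PWM":
        counts = np.asarray(counts, dtype=float)
        totals = counts.sum(axis=1, keepdims=True)
        if (totals <= 0).any():
            raise ValueError(f"PWM {name!r}: zero-count position")
        return cls(name, counts / totals, source=source)

    def reverse_complement(self) -> "PWM":
        return PWM(self.name, self.matrix[::-1, ::-1].copy(), source=self.source)

    def information_content(self) -> float:
        """Total information content in bits: sum_i (2 + sum_b p log2 p)."""
        p = np.clip(self.matrix, 1e-12, 1.0)
        return float((2.0 + (p * np.log2(p)).sum(axis=1)).sum())

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    def log_odds(self, bg: np.ndarray | None = None, pseudocount: float = 1e-3) -> np.ndarray:
        bg = UNIFORM_BG if bg is None else np.asarray(bg, dtype=float)
        bg = np.clip(bg, 1e-6, None)  # degenerate compositions stay finite
        return np.log2((self.matrix + pseudocount) / ((1.0 + 4.0 * pseudocount) * bg))

    def max_log_odds(self, bg: np.ndarray | None = None, pseudocount: float = 1e-3) -> float:
        return float(self.log_odds(bg, pseudocount).max(axis=1).sum())


@dataclass
class MotifFamily:
    """A group of TFs binding indistinguishable motifs, with one representative PWM."""

    family_id: str
    representative: PWM
    member_tf_genes: list[str]
    member_pwms: list[PWM]

    def __post_init__(self) -> None:
        names = {p.name for p in self.member_pwms}
        if self.representative.name not in names:
            raise ValueError("representative must be one of the member PWMs")
        if not self.member_tf_genes:
            raise ValueError("member_tf_genes must be non-empty")


@dataclass
class FamilyExpression:
    """Per-sample-set expression status of one family's member TF genes."""

    family_id: str
    expressed_members: list[str]
    inactive: bool


@dataclass
class MotifOccurrence:
    """A motif-family hit inside (or at the edge of) a detected footprint."""

    call_id: str
    peak_id: str
    family_id: str
    chrom: str
    start: int
    end: int
    strand: str
    score: float


def _column_correlation(x: np.ndarray, y: np.ndarray) -> float:
    # Pearson of two 4-vectors; a flat column (all 0.25) carries no base
    # preference, so its correlation with anything non-identical is 0.
    if np.allclose(x, y, atol=1e-12):
        return 1.0
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    return float(np.dot(x - x.mean(), y - y.mean()) / (4.0 * sx * sy))


def _best_alignment_score(a: np.ndarray, b: np.ndarray, min_overlap: int) -> float:
    la, lb = a.shape[0], b.shape[0]
    best = -np.inf
    for offset in range(-(lb - min_overlap), la - min_overlap + 1):
        lo = max(0, offset)
        hi = min(la, lb + offset)
        if hi - lo < min_overlap:
            continue
        cols = [_column_correlation(a[i], b[i - offset]) for i in range(lo, hi)]
        best = max(best, float(np.mean(cols)))
    return best


def pwm_similarity(a: PWM, b: PWM, min_overlap: int = 5) -> float:
    """Ungapped alignment similarity between two PWMs, in [-1, 1].

    Maximum over all offsets and both orientations of ``b`` (forward and
    reverse complement) of the mean column-wise Pearson correlation over
    the aligned overlap; at least ``min_overlap`` columns must overlap.
    Symmetric in its arguments.
    """
    if min(a.length, b.length) < min_overlap:
        raise ValueError(
            f"overlap of {min_overlap} columns unsatisfiable for PWMs of "
            f"length {a.length} and {b.length}"
        )
    fwd = _best_alignment_score(a.matrix, b.matrix, min_overlap)
    rev = _best_alignment_score(a.matrix, b.reverse_complement().matrix, min_overlap)
    return max(fwd, rev)


def condense(
    pwms: list[PWM],
    tf_annotation: dict[str, list[str]],
    threshold: float = 0.8,
    min_overlap: int = 5,
) -> list[MotifFamily]:
    """Condense a redundant PWM library into non-redundant motif families.

    Builds a graph with an edge between every PWM pair whose similarity is
    >= ``threshold``; families are the connected components.  The
    representative is the member with the highest total information
    content (ties broken by lexicographically first name) and the family
    is keyed by the representative's name.  Member TF genes are the union
    of the per-PWM annotations.
    """
    by_name = {}
    for p in pwms:
        if p.name in by_name:
            raise ValueError(f"duplicate PWM name {p.name!r}")
        by_name[p.name] = p
        if not tf_annotation.get(p.name):
            raise ValueError(f"PWM {p.name!r} has no TF gene annotation")

    g = nx.Graph()
    names = sorted(by_name)
    g.add_nodes_from(names)
    for i, na in enumerate(names):
        for nb in names[i + 1:]:
            if pwm_similarity(by_name[na], by_name[nb], min_overlap) >= threshold:
                g.add_edge(na, nb)

    families = []
    for comp in nx.connected_components(g):
        members = sorted(comp)
        rep_name = min(
            members,
            key=lambda n: (-round(by_name[n].information_content(), 9), n),
        )
        genes = sorted({gene for n in members for gene in tf_annotation[n]})
        families.append(
            MotifFamily(
                family_id=rep_name,
                representative=by_name[rep_name],
                member_tf_genes=genes,
                member_pwms=[by_name[n] for n in members],
            )
        )
    families.sort(key=lambda f: f.family_id)
    return families


def filter_expressed(
    families: list[MotifFamily],
    expression,
    samples: list[str],
    min_fkpm: float = 1.0,
) -> list[FamilyExpression]:
    """Mark each family's member TF genes as expressed over a sample set.

    A gene is expressed iff its maximum FKPM over ``samples`` is
    >= ``min_fkpm`` (inclusive).  Genes absent from the expression table
    draw a warning and count as unexpressed; a family with no expressed
    member is flagged inactive.
    """
    out = []
    for fam in families:
        expressed = []
        for gene in fam.member_tf_genes:
            if gene not in expression.index:
                warnings.warn(f"TF gene {gene!r} absent from expression table; treated unexpressed")
                continue
            if samples and float(expression.loc[gene, samples].max()) >= min_fkpm:
                expressed.append(gene)
        out.append(FamilyExpression(fam.family_id, expressed, inactive=not expressed))
    return out


def genome_base_frequencies(genome: dict[str, str]) -> np.ndarray:
    """A/C/G/T frequencies over all chromosomes (non-ACGT ignored)."""
    counts = np.zeros(4)
    for seq in genome.values():
        s = str(seq).upper()
        for i, b in enumerate(BASES):
            counts[i] += s.count(b)
    total = counts.sum()
    return counts / total if total > 0 else UNIFORM_BG.copy()


def encode_sequence(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX.get(b, -1) for b in seq.upper()], dtype=int)


def _window_scores(lom: np.ndarray, encoded: np.ndarray) -> np.ndarray:
    """Log-odds score of every window of ``encoded``; unknown bases score 0."""
    L = lom.shape[0]
    n = encoded.size - L + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    for j in range(L):
        idx = encoded[j:j + n]
        valid = idx >= 0
        scores[valid] += lom[j, idx[valid]]
    return scores


def scan_footprints(
    calls,
    genome: dict[str, str],
    families: list[MotifFamily],
    bg: np.ndarray | None = None,
    min_logodds_fraction: float = 0.8,
    flank: int = 5,
    pseudocount: float = 1e-3,
) -> list[MotifOccurrence]:
    """Scan footprint intervals (± ``flank`` bp) for family-representative motifs.

    Both strands are scored with the representative's log-odds matrix
    against the background base composition; a hit requires a score of at
    least ``min_logodds_fraction`` times the PWM's maximum achievable
    score, and only the best hit per (footprint, family) is kept.
    """
    if bg is None:
        bg = genome_base_frequencies(genome)
    loms = {f.family_id: f.representative.log_odds(bg, pseudocount) for f in families}
    max_scores = {f.family_id: f.representative.max_log_odds(bg, pseudocount) for f in families}

    occurrences = []
    for call in calls:
        chrom_seq = str(genome[call.chrom])
        if call.start < 0 or call.end > len(chrom_seq):
            raise ValueError(f"footprint {call.id} outside sequence {call.chrom}")
        lo = max(0, call.start - flank)
        hi = min(len(chrom_seq), call.end + flank)
        encoded = encode_sequence(chrom_seq[lo:hi])
        for fam in families:
            lom = loms[fam.family_id]
            L = lom.shape[0]
            fwd = _window_scores(lom, encoded)
            rev = _window_scores(lom[::-1, ::-1], encoded)
            best = None
            for strand, scores in (("+", fwd), ("-", rev)):
                if scores.size == 0:
                    continue
                pos = int(scores.argmax())
                if best is None or scores[pos] > best[2]:
                    best = (strand, pos, float(scores[pos]))
            if best is None:
                continue
            strand, pos, score = best
            if score >= min_logodds_fraction * max_scores[fam.family_id]:
                occurrences.append(
                    MotifOccurrence(
                        call_id=call.id,
                        peak_id=call.peak_id,
                        family_id=fam.family_id,
                        chrom=call.chrom,
                        start=lo + pos,
                        end=lo + pos + L,
                        strand=strand,
                        score=score,
                    )
                )
    return occurrences


def summarize_catalog(families) -> tuple[int, int]:
    """(number of families, number of distinct member TF genes) of a catalog.

    Accepts either a list of :class:`MotifFamily` or the records returned
    by :func:`footgrn.io.read_catalog_tsv`.
    """
    genes: set[str] = set()
    n = 0
    for fam in families:
        n += 1
        members = fam.member_tf_genes if hasattr(fam, "member_tf_genes") else fam["member_tf_genes"]
        genes.update(members)
    return n, len(genes)
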