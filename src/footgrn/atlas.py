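"""Union DHS atlas: peak calling on merged profiles, quantification,
rank normalization, sample clustering and subtype-specific subsets.

Merging all samples before peak calling maximizes sensitivity and
flattens background noise; every sample is then quantified on the same
fixed-width windows centered on the atlas summits, so per-sample signal
vectors are directly comparable.  Normalization anchors each sample on
the count of its peak ranked ``norm_rank`` by size (close to the median
peak in deep cohorts), which is robust to a handful of extreme peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import poisson

from footgrn.simulate import StrandedCutProfile, merge_profiles


@dataclass
class Peak:
    """A DHS atlas entry (0-based half-open)."""

    chrom: str
    start: int
    end: int
    summit: int
    id: str

    def __post_init__(self) -> None:
        if not (self.start < self.end):
            raise ValueError(f"peak {self.id}: start must be < end")
        if not (self.start <= self.summit < self.end):
            raise ValueError(f"peak {self.id}: summit outside interval")


@dataclass
class QuantConfig:
    """Quantification and normalization parameters.

    ``window_bp`` is the fixed window (400 bp) applied around each summit
    in every sample; ``norm_rank`` (16 000) is the size rank whose count
    anchors per-sample normalization; ``norm_rank_fraction`` substitutes
    a proportional rank when the atlas is smaller than ``norm_rank``
    (0.125 = 16 000 / 128 000).  ``reference_value`` fixes the target
    count at the anchor rank; by default the across-sample median of the
    anchor-rank counts is used.
    """

    window_bp: int = 400
    norm_rank: int = 16000
    norm_rank_fraction: float = 0.125
    reference_value: float | None = None

    def __post_init__(self) -> None:
        if self.window_bp <= 0 or self.window_bp % 2:
            raise ValueError("window_bp must be even and > 0")
        if self.norm_rank < 1:
            raise ValueError("norm_rank must be >= 1")

    def effective_rank(self, n_peaks: int) -> int:
        if n_peaks >= self.norm_rank:
            return self.norm_rank
        return max(1, int(np.floor(n_peaks * self.norm_rank_fraction)))


@dataclass
class CountMatrix:
    """Peak x sample window counts, raw or normalized."""

    values: pd.DataFrame  # index: peak ids, columns: sample ids
    normalized: bool = False

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")


@dataclass
class SubtypeDHSSet:
    """Peaks whose accessibility is characteristic of one subtype."""

    sets: dict[str, list[str]]
    fold: float
    presence_fraction: float
    min_signal: float


def call_peaks_merged(
    profiles: list[StrandedCutProfile],
    bin_bp: int = 50,
    p_threshold: float = 1e-5,
    merge_gap_bp: int = 200,
    smooth_bp: int = 150,
) -> list[Peak]:
    """Call peaks on the positionwise sum of all profiles (both strands).

    Fixed bins whose merged count exceeds a Poisson threshold (P[X >= c]
    < ``p_threshold`` under the genome-wide mean rate per bin) are kept;
    candidate bins separated by at most ``merge_gap_bp`` are merged into
    one region, whose summit is the argmax of the ``smooth_bp``-smoothed
    merged density (ties to the leftmost position).  Deterministic.
    """
    if not profiles:
        raise ValueError("peak calling requires at least one profile")
    merged = merge_profiles(profiles).merged_track()

    genome_len = sum(a.size for a in merged.values())
    total = sum(int(a.sum()) for a in merged.values())
    if total == 0:
        return []
    mu = total / genome_len * bin_bp

    peaks: list[Peak] = []
    for chrom in sorted(merged):
        track = merged[chrom]
        n_bins = track.size // bin_bp
        if n_bins == 0:
            continue
        bins = np.add.reduceat(track[: n_bins * bin_bp], np.arange(0, n_bins * bin_bp, bin_bp))
        candidate = poisson.sf(bins - 1, mu) < p_threshold
        idx = np.flatnonzero(candidate)
        if idx.size == 0:
            continue
        # merge candidate bins whose gap is <= merge_gap_bp
        regions = []
        start_bin = prev = idx[0]
        for b in idx[1:]:
            if (b - prev - 1) * bin_bp <= merge_gap_bp:
                prev = b
            else:
                regions.append((start_bin, prev))
                start_bin = prev = b
        regions.append((start_bin, prev))

        kernel = np.ones(smooth_bp) / smooth_bp
        smooth = np.convolve(track, kernel, mode="same")
        for rb0, rb1 in regions:
            start = int(rb0 * bin_bp)
            end = int((rb1 + 1) * bin_bp)
            summit = int(start + np.argmax(smooth[start:end]))
            peaks.append(Peak(chrom, start, end, summit, id=""))
    peaks.sort(key=lambda p: (p.chrom, p.start))
    for i, p in enumerate(peaks):
        p.id = f"peak_{i:05d}"
    return peaks


def quantify(
    atlas: list[Peak],
    profile: StrandedCutProfile,
    config: QuantConfig | None = None,
) -> pd.Series:
    """Total cuts (both strands) in the fixed window around each summit.

    Windows are ``[summit - w/2, summit + w/2)`` clipped at chromosome
    ends.
    """
    if not atlas:
        raise ValueError("atlas is empty")
    config = config or QuantConfig()
    half = config.window_bp // 2
    track = profile.merged_track()
    counts = {}
    for p in atlas:
        arr = track[p.chrom]
        lo = max(0, p.summit - half)
        hi = min(arr.size, p.summit + half)
        counts[p.id] = int(arr[lo:hi].sum())
    return pd.Series(counts, name=profile.sample_id)


def quantify_matrix(
    atlas: list[Peak],
    profiles: list[StrandedCutProfile],
    config: QuantConfig | None = None,
) -> CountMatrix:
    cols = [quantify(atlas, p, config) for p in profiles]
    return CountMatrix(pd.concat(cols, axis=1), normalized=False)


def normalize_rank(matrix: CountMatrix, config: QuantConfig | None = None) -> CountMatrix:
    """Scale each sample so its rank-``r`` largest peak count matches a
    common reference (default: the across-sample median of those counts).

    Invariant to per-sample global rescaling and idempotent when the
    reference is recomputed from the data.
    """
    config = config or QuantConfig()
    values = matrix.values.astype(float)
    r = config.effective_rank(len(values))
    rank_counts = values.apply(lambda col: float(np.sort(col.to_numpy())[::-1][r - 1]), axis=0)
    if (rank_counts == 0).any():
        shallow = list(rank_counts.index[rank_counts == 0])
        raise ValueError(f"rank-{r} count is zero for samples {shallow}; too shallow to normalize")
    reference = config.reference_value
    if reference is None:
        reference = float(np.median(rank_counts))
    factors = reference / rank_counts
    return CountMatrix(values * factors, normalized=True)


def classify_distal(
    atlas: list[Peak],
    annotation,
    promoter_margin_bp: int = 2000,
) -> list[str]:
    """Ids of peaks whose summit lies more than ``promoter_margin_bp``
    from the nearest TSS (all peaks if the annotation is empty)."""
    genes = annotation.genes if hasattr(annotation, "genes") else annotation
    tss_by_chrom = {
        c: np.sort(g["tss"].to_numpy()) for c, g in genes.groupby("chrom")
    } if len(genes) else {}
    out = []
    for p in atlas:
        tss = tss_by_chrom.get(p.chrom)
        if tss is None or tss.size == 0:
            out.append(p.id)
            continue
        j = np.searchsorted(tss, p.summit)
        dist = min(
            abs(p.summit - tss[j - 1]) if j > 0 else np.inf,
            abs(tss[j] - p.summit) if j < tss.size else np.inf,
        )
        if dist > promoter_margin_bp:
            out.append(p.id)
    return out


def cluster_samples(
    matrix: CountMatrix,
    distal_ids: list[str] | None = None,
    k: int = 2,
):
    """Average-linkage hierarchical clustering of samples on distal peaks.

    Distance is 1 - Pearson correlation of log2(1 + normalized signal).
    Returns ``(linkage_matrix, groups)`` where ``groups`` maps sample id
    to a flat cluster label from cutting the tree at ``k`` clusters;
    labels are canonicalized by sorted sample id, so the partition is
    independent of input column order.
    """
    values = matrix.values
    if distal_ids is not None:
        values = values.loc[[i for i in values.index if i in set(distal_ids)]]
    values = values[sorted(values.columns)]
    if values.shape[1] < 2:
        raise ValueError("clustering requires at least 2 samples")
    logv = np.log2(1.0 + values.to_numpy(dtype=float))
    if (logv.std(axis=0) == 0).any():
        flat = [values.columns[i] for i in np.flatnonzero(logv.std(axis=0) == 0)]
        raise ValueError(f"constant signal vector for samples {flat}; correlation undefined")
    corr = np.corrcoef(logv.T)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    raw = fcluster(z, t=k, criterion="maxclust")
    # canonical labels: first-seen order over sorted sample ids
    relabel: dict[int, int] = {}
    groups = {}
    for sample, lab in zip(values.columns, raw):
        relabel.setdefault(int(lab), len(relabel) + 1)
        groups[sample] = relabel[int(lab)]
    return z, groups


def subtype_specific_dhs(
    matrix: CountMatrix,
    metadata: pd.DataFrame,
    fold: float = 2.0,
    presence_fraction: float = 0.5,
    min_signal: float = 1.0,
) -> SubtypeDHSSet:
    """Peaks characteristic of each subtype.

    A peak belongs to subtype S iff its mean normalized signal over S
    samples is at least ``fold`` times the mean over all other samples
    (controls included) and it exceeds ``min_signal`` in at least
    ``presence_fraction`` of S samples.
    """
    values = matrix.values
    meta = metadata.set_index("sample_id")
    subtypes = sorted(s for s in meta["subtype"].unique() if not meta[meta["subtype"] == s]["is_control"].all())
    sets: dict[str, list[str]] = {}
    for s in subtypes:
        in_s = [c for c in values.columns if meta.loc[c, "subtype"] == s]
        out_s = [c for c in values.columns if c not in in_s]
        if not in_s:
            raise ValueError(f"subtype {s!r} has no samples")
        mean_in = values[in_s].mean(axis=1)
        mean_out = values[out_s].mean(axis=1) if out_s else pd.Series(0.0, index=values.index)
        present = (values[in_s] > min_signal).mean(axis=1) >= presence_fraction
        chosen = values.index[(mean_in >= fold * mean_out) & present]
        sets[s] = sorted(chosen)
    return SubtypeDHSSet(sets=sets, fold=fold, presence_fraction=presence_fraction,
                         min_signal=min_signal)
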