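"""Digital footprint detection inside DHSs, plus sequencing-depth QC.

A bound protein protects its motif from DNase I cleavage, leaving a
short interval of depleted cuts flanked by intact (or elevated) cut
density.  For a candidate footprint of length L with shoulders of S bp,
the forward-strand statistic asks how surprising the observed split of
forward cuts between the upstream shoulder and the footprint interior
is under a uniform cut rate: with f_sh shoulder cuts and f_fp interior
cuts, p = P[X >= f_sh] for X ~ Binomial(f_sh + f_fp, S / (S + L)).  The
reverse strand is tested symmetrically against the downstream shoulder,
and the combined score is the minimum of the two -log10 p values, so
both strands must individually support the protection signature.

Depth QC: raw read depth is a poor predictor of footprint detectability;
the median cut count within the fixed peak window ("peak volume") tracks
it much better, with roughly one footprint per peak detectable once the
median volume reaches ~700 cuts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom

from footgrn.atlas import Peak, QuantConfig, quantify
from footgrn.simulate import StrandedCutProfile

_LN10 = np.log(10.0)


@dataclass
class FootprintParams:
    """Detection parameters; all constants of the statistic are exposed."""

    footprint_lengths: tuple[int, int] = (11, 25)  # inclusive range
    shoulder_bp: int = 35
    score_threshold: float = 10.0
    max_footprints_per_peak: int | None = None
    window_bp: int = 400

    def __post_init__(self) -> None:
        if self.shoulder_bp <= 0:
            raise ValueError("shoulder_bp must be > 0")
        if self.footprint_lengths[0] < 6:
            raise ValueError("footprint lengths must be >= 6")
        if self.footprint_lengths[0] > self.footprint_lengths[1]:
            raise ValueError("invalid footprint length range")

    @property
    def lengths(self) -> range:
        return range(self.footprint_lengths[0], self.footprint_lengths[1] + 1)


@dataclass
class FootprintCall:
    """A scored, strand-supported protected interval inside a peak."""

    id: str
    peak_id: str
    chrom: str
    start: int
    end: int
    score: float
    forward_score: float
    reverse_score: float


@dataclass
class FootprintQCRecord:
    """One subsampling level of the depth-QC curve."""

    sample_id: str
    fraction: float
    total_reads: int
    median_peak_volume: float
    footprints_per_peak: float


def wellington_from_counts(shoulder_cuts: int, footprint_cuts: int, length: int, shoulder_bp: int) -> float:
    """-log10 P[X >= shoulder_cuts], X ~ Binom(n, S/(S+L)) with
    n = shoulder + footprint cuts; defined as 0 when n = 0."""
    n = shoulder_cuts + footprint_cuts
    if n == 0:
        return 0.0
    p = shoulder_bp / (shoulder_bp + length)
    return float(-binom.logsf(shoulder_cuts - 1, n, p) / _LN10)


def wellington_score(
    profile: StrandedCutProfile,
    peak: Peak,
    fp_interval: tuple[int, int],
    params: FootprintParams | None = None,
) -> tuple[float, float, float]:
    """(forward, reverse, combined) footprint scores for one interval.

    Forward uses forward-strand cuts in the footprint and the upstream
    shoulder ``[start - S, start)``; reverse uses reverse-strand cuts in
    the footprint and the downstream shoulder ``[end, end + S)``.  The
    combined score is the minimum of the two.
    """
    params = params or FootprintParams()
    start, end = fp_interval
    L = end - start
    S = params.shoulder_bp
    fwd = profile.fwd[peak.chrom]
    rev = profile.rev[peak.chrom]
    if start - S < 0 or end + S > fwd.size:
        raise ValueError("footprint lacks shoulder clearance within the chromosome")
    f_sh = int(fwd[start - S:start].sum())
    f_fp = int(fwd[start:end].sum())
    r_sh = int(rev[end:end + S].sum())
    r_fp = int(rev[start:end].sum())
    s_f = wellington_from_counts(f_sh, f_fp, L, S)
    s_r = wellington_from_counts(r_sh, r_fp, L, S)
    return s_f, s_r, min(s_f, s_r)


def _strand_scores(cum: np.ndarray, starts: np.ndarray, L: int, S: int, upstream: bool) -> np.ndarray:
    """Vectorized -log10 binomial tail for all candidate starts at one length."""
    interior = cum[starts + L] - cum[starts]
    if upstream:
        shoulder = cum[starts] - cum[starts - S]
    else:
        shoulder = cum[np.minimum(starts + L + S, cum.size - 1)] - cum[starts + L]
    n = shoulder + interior
    p = S / (S + L)
    with np.errstate(divide="ignore"):
        scores = -binom.logsf(shoulder - 1, np.maximum(n, 1), p) / _LN10
    scores[n == 0] = 0.0
    return scores


def detect_footprints(
    profile: StrandedCutProfile,
    atlas: list[Peak],
    params: FootprintParams | None = None,
) -> list[FootprintCall]:
    """Score every candidate (position, length) inside each peak window and
    greedily accept non-overlapping calls above the score threshold.

    Candidates are ranked by descending combined score with deterministic
    tie-breaking (leftmost start, then shortest length).
    """
    params = params or FootprintParams()
    S = params.shoulder_bp
    half = params.window_bp // 2
    calls: list[FootprintCall] = []
    for peak in atlas:
        fwd = profile.fwd[peak.chrom]
        rev = profile.rev[peak.chrom]
        win_lo = max(S, peak.summit - half)
        win_hi = min(fwd.size - S, peak.summit + half)
        if win_hi - win_lo < params.footprint_lengths[0]:
            continue
        cf = np.concatenate([[0], np.cumsum(fwd)])
        cr = np.concatenate([[0], np.cumsum(rev)])
        candidates = []
        for L in params.lengths:
            starts = np.arange(win_lo, win_hi - L + 1)
            if starts.size == 0:
                continue
            sf = _strand_scores(cf, starts, L, S, upstream=True)
            sr = _strand_scores(cr, starts, L, S, upstream=False)
            combined = np.minimum(sf, sr)
            keep = np.flatnonzero(combined >= params.score_threshold)
            for i in keep:
                candidates.append(
                    (float(combined[i]), int(starts[i]), L, float(sf[i]), float(sr[i]))
                )
        candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
        accepted: list[tuple[int, int]] = []
        for score, start, L, s_f, s_r in candidates:
            if params.max_footprints_per_peak is not None and \
                    len(accepted) >= params.max_footprints_per_peak:
                break
            end = start + L
            if any(start < e and s < end for s, e in accepted):
                continue
            accepted.append((start, end))
            calls.append(FootprintCall(
                id="", peak_id=peak.id, chrom=peak.chrom,
                start=start, end=end, score=score,
                forward_score=s_f, reverse_score=s_r,
            ))
    calls.sort(key=lambda c: (c.chrom, c.start, c.end))
    for i, c in enumerate(calls):
        c.id = f"fp_{i:05d}"
    return calls


def qc_curve(
    profile: StrandedCutProfile,
    atlas: list[Peak],
    params: FootprintParams | None = None,
    fractions: tuple[float, ...] = (0.05, 0.1, 0.25, 0.5, 1.0),
    seed: int = 0,
    quant_config: QuantConfig | None = None,
) -> tuple[list[FootprintQCRecord], float | None]:
    """Depth-QC curve by nested binomial thinning of one profile.

    Fractions are applied as a nested chain (each level is a further
    thinning of the previous one, so lower fractions are true subsets)
    with a fixed seed.  For each level the record holds the total cuts,
    the median peak volume in the fixed quantification window, and the
    mean number of footprint calls per peak.  The recommended minimum
    volume is the smallest observed median volume whose level reaches at
    least 1 footprint per peak (None if never reached).
    """
    if not atlas:
        raise ValueError("atlas is empty")
    params = params or FootprintParams()
    quant_config = quant_config or QuantConfig(window_bp=params.window_bp)
    fracs = sorted(set(fractions), reverse=True)
    if any(not 0.0 <= f <= 1.0 for f in fracs):
        raise ValueError("fractions must be in [0, 1]")

    records: list[FootprintQCRecord] = []
    current = profile
    current_frac = 1.0
    for k, f in enumerate(fracs):
        conditional = f / current_frac
        current = current.thin(conditional, seed=[seed, k])
        current_frac = f
        volumes = quantify(atlas, current, quant_config)
        n_calls = len(detect_footprints(current, atlas, params))
        records.append(FootprintQCRecord(
            sample_id=profile.sample_id,
            fraction=f,
            total_reads=current.total_cuts(),
            median_peak_volume=float(volumes.median()),
            footprints_per_peak=n_calls / len(atlas),
        ))
    records.sort(key=lambda r: r.fraction)
    eligible = [r.median_peak_volume for r in records if r.footprints_per_peak >= 1.0]
    recommended = min(eligible) if eligible and len(records) > 1 else None
    return records, recommended
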