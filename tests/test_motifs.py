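"""PWM similarity against a brute-force oracle, family condensation
properties, expression filtering, motif scanning, catalog summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from footgrn.motifs import (
    PWM,
    condense,
    filter_expressed,
    genome_base_frequencies,
    pwm_similarity,
    scan_footprints,
    summarize_catalog,
)


def random_pwm(rng, length, name="m", peaked=True):
    if peaked:
        mat = np.full((length, 4), 0.03)
        mat[np.arange(length), rng.integers(0, 4, length)] = 0.91
    else:
        mat = rng.dirichlet(np.ones(4), size=length)
    return PWM(name, mat)


def point_mass(name, consensus):
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    mat = np.zeros((len(consensus), 4))
    for i, b in enumerate(consensus):
        mat[i, idx[b]] = 1.0
    return PWM(name, mat)


def similarity_oracle(a: PWM, b: PWM, min_overlap=5) -> float:
    """Independent exhaustive enumeration over offsets and orientations."""
    def corr(x, y):
        if np.allclose(x, y, atol=1e-12):
            return 1.0
        if x.std() == 0 or y.std() == 0:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1])

    best = -np.inf
    for bmat in (b.matrix, b.matrix[::-1, ::-1]):
        la, lb = a.matrix.shape[0], bmat.shape[0]
        for offset in range(-lb + 1, la):
            cols = []
            for i in range(la):
                j = i - offset
                if 0 <= j < lb:
                    cols.append(corr(a.matrix[i], bmat[j]))
            if len(cols) >= min_overlap:
                best = max(best, float(np.mean(cols)))
    return best


class TestSimilarity:
    def test_identical_pwms_score_exactly_one(self, rng):
        p = random_pwm(rng, 10)
        assert pwm_similarity(p, p) == 1.0

    def test_reverse_complement_scores_one(self, rng):
        p = random_pwm(rng, 12)
        assert pwm_similarity(p, p.reverse_complement()) == pytest.approx(1.0)

    def test_symmetry(self, rng):
        for _ in range(10):
            a = random_pwm(rng, int(rng.integers(6, 14)), peaked=False)
            b = random_pwm(rng, int(rng.integers(6, 14)), peaked=False)
            assert pwm_similarity(a, b) == pytest.approx(pwm_similarity(b, a), abs=1e-12)

    def test_point_mass_vs_uniform_matches_oracle(self):
        a = point_mass("acgt", "ACGTACGT")
        b = PWM("uniform", np.full((8, 4), 0.25))
        assert pwm_similarity(a, b) == pytest.approx(similarity_oracle(a, b), abs=1e-12)

    def test_matches_bruteforce_oracle_on_random_pairs(self, rng):
        for _ in range(25):
            a = random_pwm(rng, int(rng.integers(5, 15)), peaked=bool(rng.integers(2)))
            b = random_pwm(rng, int(rng.integers(5, 15)), peaked=bool(rng.integers(2)))
            assert pwm_similarity(a, b) == pytest.approx(
                similarity_oracle(a, b), abs=1e-9)

    def test_unsatisfiable_overlap_raises(self):
        a = point_mass("a", "ACGT")
        with pytest.raises(ValueError, match="unsatisfiable"):
            pwm_similarity(a, a, min_overlap=5)


class TestCondense:
    def _library(self):
        a = point_mass("A0", "ACGTTGCACGTA")
        shifted = PWM("A_shift", np.vstack([a.matrix[2:], a.matrix[:2]]))
        rc = PWM("A_rc", a.reverse_complement().matrix)
        b = point_mass("B0", "TTATAGCCGGAA")
        ann = {"A0": ["GENE_A"], "A_shift": ["GENE_A2"],
               "A_rc": ["GENE_A"], "B0": ["GENE_B"]}
        return [a, shifted, rc, b], ann

    def test_worked_four_pwm_example_gives_two_families(self):
        pwms, ann = self._library()
        fams = condense(pwms, ann)
        assert len(fams) == 2
        sizes = sorted(len(f.member_pwms) for f in fams)
        assert sizes == [1, 3]

    def test_single_pwm_is_its_own_representative(self):
        p = point_mass("solo", "ACGTAC")
        fams = condense([p], {"solo": ["G1"]})
        assert len(fams) == 1
        assert fams[0].representative.name == "solo"
        assert fams[0].member_tf_genes == ["G1"]

    def test_threshold_above_one_splits_everything(self):
        pwms, ann = self._library()
        fams = condense(pwms, ann, threshold=1.01)
        assert len(fams) == len(pwms)

    def test_partition_property(self, cohort):
        truth = cohort["truth"]
        fams = condense(truth.pwms, truth.tf_annotation)
        seen = [p.name for f in fams for p in f.member_pwms]
        assert sorted(seen) == sorted(p.name for p in truth.pwms)

    def test_input_order_and_orientation_invariance(self):
        pwms, ann = self._library()
        base = condense(pwms, ann)
        reordered = condense(list(reversed(pwms)), ann)
        flipped = condense(
            [PWM(p.name, p.reverse_complement().matrix) for p in pwms], ann)
        def partition(fams):
            return {frozenset(p.name for p in f.member_pwms) for f in fams}
        assert partition(base) == partition(reordered) == partition(flipped)

    def test_unannotated_pwm_rejected(self):
        p = point_mass("x", "ACGTA")
        with pytest.raises(ValueError, match="annotation"):
            condense([p], {})


class TestFilterExpressed:
    def _families(self):
        p = point_mass("rep", "ACGTAA")
        from footgrn.motifs import MotifFamily
        return [MotifFamily("rep", p, ["G1", "G2"], [p])]

    def test_all_zero_expression_flags_inactive(self):
        expr = pd.DataFrame({"s1": [0.0, 0.0]}, index=["G1", "G2"])
        out = filter_expressed(self._families(), expr, ["s1"])
        assert out[0].inactive and out[0].expressed_members == []

    def test_threshold_is_inclusive(self):
        expr = pd.DataFrame({"s1": [1.0, 0.99]}, index=["G1", "G2"])
        out = filter_expressed(self._families(), expr, ["s1"], min_fkpm=1.0)
        assert out[0].expressed_members == ["G1"]

    def test_missing_gene_warns_and_is_unexpressed(self):
        expr = pd.DataFrame({"s1": [5.0]}, index=["G1"])
        with pytest.warns(UserWarning, match="absent"):
            out = filter_expressed(self._families(), expr, ["s1"])
        assert out[0].expressed_members == ["G1"]

    def test_planted_upregulated_tfs_always_expressed(self, cohort):
        truth, cfg = cohort["truth"], cohort["config"]
        fams = condense(truth.pwms, truth.tf_annotation)
        meta = cohort["metadata"]
        for s in cfg.subtypes:
            samples = list(meta[meta["subtype"] == s]["sample_id"])
            out = filter_expressed(fams, cohort["expression"], samples)
            expressed = {g for fe in out for g in fe.expressed_members}
            assert set(truth.upregulated[s]) <= expressed


class _Call:
    def __init__(self, id, chrom, start, end, peak_id="pk"):
        self.id, self.chrom, self.start, self.end, self.peak_id = \
            id, chrom, start, end, peak_id


class TestScan:
    def test_embedded_consensus_scores_maximum(self, cohort):
        truth = cohort["truth"]
        fams = condense(truth.pwms, truth.tf_annotation)
        genome = truth.annotation.sequences()
        fp = truth.footprints.iloc[0]
        call = _Call("c0", fp.chrom, int(fp.start), int(fp.end), fp.peak_id)
        occs = scan_footprints([call], genome, fams)
        planted_rep = truth.families[fp.family_id]["representative"]
        best = {o.family_id: o for o in occs}
        assert planted_rep in best
        rep = next(f for f in fams if f.family_id == planted_rep).representative
        bg = genome_base_frequencies(genome)
        # consensus embedding scores the maximum achievable log-odds
        assert best[planted_rep].score == pytest.approx(
            rep.max_log_odds(bg), rel=1e-9)

    def test_empty_call_list(self, cohort):
        truth = cohort["truth"]
        fams = condense(truth.pwms, truth.tf_annotation)
        assert scan_footprints([], truth.annotation.sequences(), fams) == []

    def test_call_outside_sequence_raises(self):
        fam = condense([point_mass("m", "ACGTACGT")], {"m": ["G"]})
        with pytest.raises(ValueError, match="outside"):
            scan_footprints([_Call("c", "chr1", 995, 1010)], {"chr1": "A" * 1000}, fam)

    def test_agrees_with_positionwise_bruteforce(self, rng):
        """Best hit and threshold decisions match a naive per-position scorer
        on a 1-kb random sequence with a point-mass 8-mer."""
        seq = "".join(rng.choice(list("ACGT"), 1000))
        genome = {"chr1": seq}
        pwm = point_mass("m8", "ACGTTGCA")
        fams = condense([pwm], {"m8": ["G"]})
        rep = fams[0].representative
        bg = genome_base_frequencies(genome)
        lom = rep.log_odds(bg)
        comp = str.maketrans("ACGT", "TGCA")
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}

        def naive_best(lo, hi):
            best = None
            window = seq[lo:hi]
            for strand in "+-":
                s = window if strand == "+" else window.translate(comp)[::-1]
                for off in range(len(window) - 8 + 1):
                    sub = s[off:off + 8] if strand == "+" else \
                        window[off:off + 8].translate(comp)[::-1]
                    score = sum(lom[i, idx[b]] for i, b in enumerate(sub))
                    if best is None or score > best:
                        best = score
            return best

        hits = 0
        for start in range(0, 960, 20):
            call = _Call(f"c{start}", "chr1", start + 5, start + 15)
            occs = scan_footprints([call], genome, fams)
            expect = naive_best(start, start + 20)
            if occs:
                hits += 1
                assert occs[0].score == pytest.approx(expect, rel=1e-9)
            else:
                assert expect < 0.8 * rep.max_log_odds(bg)
        # chance hits of a strict 8-mer at threshold 0.8 of max are rare
        assert hits <= 3


class TestSummarize:
    def test_empty_catalog(self):
        assert summarize_catalog([]) == (0, 0)

    def test_shared_gene_counted_once(self):
        from footgrn.motifs import MotifFamily
        a, b = point_mass("a", "ACGTA"), point_mass("b", "TTTAA")
        fams = [MotifFamily("a", a, ["G1", "G2"], [a]),
                MotifFamily("b", b, ["G2", "G3"], [b])]
        assert summarize_catalog(fams) == (2, 3)

    def test_tsv_roundtrip_and_parse_error_line(self, tmp_path):
        from footgrn.io import read_catalog_tsv, write_catalog_tsv
        from footgrn.motifs import MotifFamily
        a = point_mass("a", "ACGTA")
        write_catalog_tsv([MotifFamily("a", a, ["G1", "G2"], [a])],
                          tmp_path / "cat.tsv")
        records = read_catalog_tsv(tmp_path / "cat.tsv")
        assert summarize_catalog(records) == (1, 2)
        bad = tmp_path / "bad.tsv"
        bad.write_text("family_id\tmember_tf_genes\nf1\tG1;G2\nonly_one_field\n")
        with pytest.raises(ValueError, match="line 3"):
            read_catalog_tsv(bad)
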