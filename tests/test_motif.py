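"""PWM construction, scanning against a brute-force oracle, calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peakscan import DimericPWM, build_pwm, scan_sequence
from peakscan.genomics import reverse_complement
from peakscan.motif import (
    SCORE_FLOOR,
    batch_best_scores,
    calibrate_threshold,
    compare_scanners,
    estimate_fdr,
    read_meme,
    roc_auc,
    write_meme,
)

BASE_IDX = {b: i for i, b in enumerate("ACGT")}


def brute_force_best(pwm: DimericPWM, seq: str) -> float:
    """Independent enumeration of every placement, strand and spacer."""

    def col_score(col, base, bg):
        if base not in BASE_IDX:
            return 0.0
        p = col[BASE_IDX[base]]
        return SCORE_FLOOR if p == 0 else math.log2(p / bg[BASE_IDX[base]])

    def score_at(s, pos, spacer):
        total = 0.0
        cols = list(pwm.half_a) + [None] * spacer + list(pwm.half_b)
        for j, col in enumerate(cols):
            if col is None:
                continue
            total += col_score(col, s[pos + j], pwm.background)
        return total

    best = -math.inf
    for s in (seq.upper(), reverse_complement(seq.upper())):
        for spacer in range(pwm.spacer_range[0], pwm.spacer_range[1] + 1):
            span = pwm.span(spacer)
            for pos in range(len(s) - span + 1):
                best = max(best, score_at(s, pos, spacer))
    return best


def random_pwm(rng, w_a, w_b, spacer_range):
    def mat(w):
        m = rng.dirichlet(np.ones(4) * 0.7, size=w)
        return m

    bg = rng.dirichlet(np.ones(4) * 10)
    return DimericPWM(mat(w_a), mat(w_b), spacer_range, bg)


class TestBuildPwm:
    def test_hand_computed_frequencies(self):
        pwm = build_pwm(["ACGT", "ACGT"], pseudocount=0.25)
        assert pwm.half_a[0, BASE_IDX["A"]] == pytest.approx(2.25 / 3)
        assert np.allclose(pwm.half_a.sum(axis=1), 1.0)

    def test_zero_pseudocount_floor(self):
        pwm = build_pwm(["A", "A"], pseudocount=0.0)
        lo = pwm.log_odds(0)
        assert lo[0, BASE_IDX["C"]] == SCORE_FLOOR
        assert lo[0, 4] == 0.0  # N contributes nothing

    def test_uniform_columns(self):
        pwm = build_pwm(["A", "C", "G", "T"], pseudocount=0.0)
        assert np.allclose(pwm.half_a, 0.25)

    def test_validation(self):
        with pytest.raises(ValueError):
            build_pwm([])
        with pytest.raises(ValueError):
            build_pwm(["ACG", "AC"])


class TestScan:
    def test_hand_computed_best(self):
        pwm = build_pwm(["ACGT", "ACGT"], pseudocount=0.25)
        res = scan_sequence(pwm, "ACGT")
        assert res.best.score == pytest.approx(4 * math.log2(0.75 / 0.25))
        assert (res.best.position, res.best.strand) == (0, "+")

    def test_too_short(self):
        pwm = build_pwm(["ACGTACGT"])
        res = scan_sequence(pwm, "ACG")
        assert res.too_short and res.best is None and res.hits == ()

    @given(st.text(alphabet="ACGTN", min_size=8, max_size=60))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_strand_symmetry(self, seq):
        pwm = build_pwm(["ACGTTGCA", "AGGTTGCA", "ACGTTGCT"], split=4)
        fwd = batch_best_scores(pwm, [seq])[0]
        rev = batch_best_scores(pwm, [reverse_complement(seq)])[0]
        assert fwd == pytest.approx(rev, abs=1e-9) or (
            np.isinf(fwd) and np.isinf(rev)
        )

    def test_matches_bruteforce_enumeration(self, rng):
        for trial in range(100):
            w_a = int(rng.integers(3, 7))
            w_b = int(rng.integers(0, 5))
            spacer = (0, int(rng.integers(0, 3))) if w_b else (0, 0)
            pwm = random_pwm(rng, w_a, w_b, spacer)
            L = int(rng.integers(pwm.min_span, 51))
            seq = "".join(rng.choice(list("ACGTN"), p=[0.24, 0.24, 0.24, 0.24, 0.04], size=L))
            got = batch_best_scores(pwm, [seq])[0]
            want = brute_force_best(pwm, seq)
            assert got == pytest.approx(want, abs=1e-9), (trial, seq)

    def test_all_hits_reported_above_threshold(self):
        pwm = build_pwm(["ACGT"])
        res = scan_sequence(pwm, "ACGTACGT", threshold=4.0)
        assert {h.position for h in res.hits} == {0, 4}
        assert all(h.score >= 4.0 for h in res.hits)


class TestCalibration:
    def test_perfect_separation(self):
        cal = calibrate_threshold([5, 6, 7], [1, 2, 3])
        assert cal.threshold == 5 and cal.f_measure == 1.0

    def test_identical_distributions_cap(self):
        cal = calibrate_threshold([1, 2, 3], [1, 2, 3])
        assert cal.f_measure <= 2 / 3 + 1e-12

    def test_matches_bruteforce_sweep(self, rng):
        def oracle(pos, bg):
            best = (-1.0, None)
            for t in sorted(set(pos) | set(bg)):
                tp = sum(p >= t for p in pos)
                fp = sum(b >= t for b in bg)
                fn = len(pos) - tp
                if tp == 0:
                    f = 0.0
                else:
                    prec, rec = tp / (tp + fp), tp / (tp + fn)
                    f = 2 * prec * rec / (prec + rec)
                if f > best[0]:
                    best = (f, t)
            return best

        for _ in range(20):
            pos = list(rng.normal(1, 1, size=25))
            bg = list(rng.normal(0, 1, size=25))
            f_star, t_star = oracle(pos, bg)
            cal = calibrate_threshold(pos, bg)
            assert cal.f_measure == pytest.approx(f_star)
            assert cal.threshold == pytest.approx(t_star)

    def test_degenerate_warns(self):
        with pytest.warns(UserWarning):
            cal = calibrate_threshold([2.0, 2.0], [2.0])
        assert cal.threshold == 2.0


class TestFdrEstimate:
    def test_by_definition(self):
        # bg rate 0.1, pos rate 0.5 at threshold 10 -> 0.2
        pos = [11] * 5 + [1] * 5
        bg = [11] * 1 + [1] * 9
        assert estimate_fdr(10, pos, bg) == pytest.approx(0.2)

    def test_no_calls_convention(self):
        assert estimate_fdr(100, [1, 2], [1, 2]) == 1.0

    def test_clean_background(self):
        assert estimate_fdr(5, [6, 7], [1, 2]) == 0.0


class TestRocAuc:
    def test_identical_distributions(self):
        assert roc_auc([1, 2, 3], [1, 2, 3]) == pytest.approx(0.5)

    def test_pair_enumeration(self):
        assert roc_auc([2, 4], [1, 3]) == pytest.approx(0.75)

    def test_rank_invariance(self, rng):
        pos = rng.normal(1, 1, 50)
        bg = rng.normal(0, 1, 50)
        assert roc_auc(pos, bg) == pytest.approx(
            roc_auc(np.exp(pos), np.exp(bg))
        )


class TestCompareScanners:
    def test_scanner_vs_itself(self):
        pwm = build_pwm(["ACGTAC", "ACGTAC", "ACGAAC"])
        fn = lambda s: float(batch_best_scores(pwm, [s])[0])  # noqa: E731
        seqs_pos = ["ACGTACGT", "TTACGTAC", "GGGGGGGG"]
        seqs_bg = ["TTTTTTTT", "CCCCCCCC", "GTGTGTGT"]
        table = compare_scanners([("a", fn), ("b", fn)], seqs_pos, seqs_bg)
        assert (table.loc["a"] == table.loc["b"]).all()

    def test_random_scanner_diagonal(self, rng):
        state = {"i": 0}
        vals = rng.random(2000)

        def random_scorer(_):
            state["i"] += 1
            return float(vals[state["i"] - 1])

        seqs = ["ACGT"] * 500
        table = compare_scanners([("rand", random_scorer)], seqs, seqs)
        row = table.loc["rand"]
        assert row.sensitivity == pytest.approx(1 - row.specificity, abs=0.1)

    def test_true_pwm_beats_corrupted(self, rng):
        from peakscan import simulate

        pwm = simulate.default_dimeric_pwm()
        corrupt = DimericPWM(
            np.roll(pwm.half_a, 3, axis=0),
            np.roll(pwm.half_b, 5, axis=0),
            pwm.spacer_range,
            pwm.background,
        )
        pos = []
        for _ in range(300):
            bgseq = "".join(rng.choice(list("ACGT"), size=60))
            inst = simulate.sample_motif_instance(pwm, rng)
            pos.append(bgseq[:20] + inst + bgseq[40:])
        bg = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(300)]
        table = compare_scanners(
            [
                ("true", lambda s: float(batch_best_scores(pwm, [s])[0])),
                ("corrupt", lambda s: float(batch_best_scores(corrupt, [s])[0])),
            ],
            pos,
            bg,
        )
        assert table.loc["true", "sensitivity"] >= table.loc["corrupt", "sensitivity"]
        assert table.loc["true", "specificity"] >= 0.8


class TestMemeIO:
    def test_roundtrip_with_dimer_sidecar(self, tmp_path, rng):
        pwm = random_pwm(rng, 6, 6, (0, 2))
        pwm2 = random_pwm(rng, 8, 0, (0, 0))
        path = tmp_path / "motifs.meme"
        write_meme({"dimer": pwm, "block": pwm2}, path)
        back = read_meme(path)
        assert set(back) == {"dimer", "block"}
        assert np.allclose(back["dimer"].half_a, pwm.half_a, atol=1e-5)
        assert np.allclose(back["dimer"].half_b, pwm.half_b, atol=1e-5)
        assert back["dimer"].spacer_range == (0, 2)
        assert back["block"].width_b == 0
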