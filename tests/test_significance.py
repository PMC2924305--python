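"""Train/eval split, backgrounds, enrichment statistics and discovery."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import comb

from peakscan import Genome, GenomicInterval, simulate
from peakscan.motif import batch_best_scores, build_pwm
from peakscan.significance import (
    MotifCandidate,
    NoSignificantMotifError,
    _hyper_upper,
    bh_correct,
    binomial_overrepresentation,
    discover_motifs,
    evaluate_candidates,
    markov_background,
    motif_enrichment,
    sample_genomic_background,
    select_best_motif,
    split_train_eval,
)


def enum_hypergeom_upper(x, N, K, n):
    """Brute-force urn enumeration of P(X >= x)."""
    total = comb(N, n, exact=True)
    acc = 0
    for k in range(x, min(K, n) + 1):
        acc += comb(K, k, exact=True) * comb(N - K, n - k, exact=True)
    return acc / total


def enum_binom_upper(x, n, p):
    return sum(comb(n, k, exact=True) * p**k * (1 - p) ** (n - k) for k in range(x, n + 1))


@pytest.fixture(scope="module")
def peak_set(toy_genome_dict):
    peaks, truth, genome = simulate.plant_peaks(
        dict(toy_genome_dict), 40, planting_rate=1.0, seed=5
    )
    return peaks, Genome(genome)


class TestSplit:
    def test_small_even_split(self, peak_set):
        peaks, genome = peak_set
        train, evals = split_train_eval(peaks[:4], genome, 0.5, window=200, seed=1)
        assert len(train) == 2 and len(evals) == 2

    def test_deterministic_and_exhaustive(self, peak_set):
        peaks, genome = peak_set
        t1, e1 = split_train_eval(peaks, genome, 0.2, seed=9)
        t2, e2 = split_train_eval(peaks, genome, 0.2, seed=9)
        assert t1 == t2 and e1 == e2
        assert len(t1) + len(e1) == len(peaks)
        assert sorted(t1 + e1) == sorted(
            t2 + e2
        )

    def test_window_centred_on_summit(self, peak_set):
        peaks, genome = peak_set
        train, evals = split_train_eval(peaks, genome, 0.5, window=100, seed=0)
        assert all(len(s) == 100 for s in train + evals)


class TestGenomicBackground:
    def test_matches_template_lengths_and_chromosomes(self, toy_genome):
        templates = [GenomicInterval("chrA", i * 500, i * 500 + 200) for i in range(60)]
        templates += [GenomicInterval("chrB", i * 500, i * 500 + 200) for i in range(40)]
        regions = sample_genomic_background(toy_genome, templates, 1000, seed=3)
        assert all(r.length() == 200 for r in regions)
        n_a = sum(r.chrom == "chrA" for r in regions)
        assert abs(n_a - 600) <= 2  # proportional allocation
        assert len(regions) == 1000

    def test_exclusion_respected(self, toy_genome):
        templates = [GenomicInterval("chrA", 0, 200)]
        block = [GenomicInterval("chrA", 0, 20_000)]
        regions = sample_genomic_background(
            toy_genome, templates, 50, seed=1, exclude=block
        )
        assert all(not r.overlaps(block[0]) for r in regions)

    def test_infeasible_exclusion_errors(self, toy_genome):
        templates = [GenomicInterval("chrA", 0, 200)]
        whole = [
            GenomicInterval(c, 0, toy_genome.chrom_length(c))
            for c in toy_genome.chromosomes()
        ]
        with pytest.raises(RuntimeError):
            sample_genomic_background(
                toy_genome, templates, 5, seed=1, exclude=whole,
                max_tries_per_region=50,
            )


class TestMarkovBackground:
    def test_absorbing_chain(self):
        out = markov_background(["A" * 200], order=1, n=20, length=100, seed=0)
        frac_a = np.mean([s.count("A") / len(s) for s in out])
        assert frac_a > 0.95  # smoothing leakage < 5%

    def test_dinucleotide_frequencies_converge(self, rng):
        train = [
            "".join(rng.choice(list("ACGT"), p=[0.4, 0.1, 0.2, 0.3], size=300))
            for _ in range(100)
        ]
        gen = markov_background(train, order=1, n=600, length=200, seed=1)

        def difreq(seqs):
            c = np.zeros((4, 4))
            idx = {b: i for i, b in enumerate("ACGT")}
            for s in seqs:
                for a, b in zip(s, s[1:]):
                    c[idx[a], idx[b]] += 1
            return (c / c.sum()).ravel()

        assert np.abs(difreq(train) - difreq(gen)).sum() < 0.02

    def test_order_zero_iid(self):
        out = markov_background(["AACC" * 100], order=0, n=200, length=100, seed=2)
        joined = "".join(out)
        assert abs(joined.count("A") / len(joined) - 0.5) < 0.03
        assert joined.count("G") / len(joined) < 0.05


class TestHypergeometricEnrichment:
    def test_worked_example(self):
        # 5 eval + 5 bg, 4 eval hits, 0 bg hits
        assert _hyper_upper(4, 10, 4, 5) == pytest.approx(6 / 252)

    def test_identical_sets_null(self):
        pwm = build_pwm(["ACGTACGT"])
        cand = MotifCandidate(pwm)
        seqs = ["ACGTACGTAA", "TTTTTTTTTT", "ACGTACGTCC", "GGGGGGGGGG"]
        res = motif_enrichment(cand, seqs, seqs, seqs, threshold=10.0)
        assert res.fold_genomic == pytest.approx(1.0)
        assert res.p_hyper >= 0.5

    @given(st.data())
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_matches_enumeration_all_small_urns(self, data):
        N = data.draw(st.integers(2, 20))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(1, N))
        x = data.draw(st.integers(0, min(K, n)))
        assert _hyper_upper(x, N, K, n) == pytest.approx(
            enum_hypergeom_upper(x, N, K, n), abs=1e-12
        )


class TestBhCorrection:
    def test_hand_stepup(self):
        assert np.allclose(bh_correct([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_and_saturated(self):
        assert bh_correct([0.2])[0] == pytest.approx(0.2)
        assert np.allclose(bh_correct([1.0, 1.0, 1.0]), 1.0)

    def test_order_invariance_and_bounds(self, rng):
        p = rng.random(30)
        perm = rng.permutation(30)
        adjusted = bh_correct(p)
        assert np.allclose(bh_correct(p[perm]), adjusted[perm])
        # step-up output is monotone in rank, dominates raw p, capped at 1
        order = np.argsort(p)
        assert (np.diff(adjusted[order]) >= -1e-12).all()
        assert (adjusted >= p).all() and (adjusted <= 1).all()


class TestSelection:
    def _result(self, auc, significant, width=8, consensus_seed=0):
        from peakscan.significance import EnrichmentResult

        rng = np.random.default_rng(consensus_seed)
        word = "".join(rng.choice(list("ACGT"), size=width))
        cand = MotifCandidate(build_pwm([word]))
        res = EnrichmentResult(0.0001, 0.0005, 2.0, 2.0, significant, auc, 5.0)
        return cand, res

    def test_highest_auc_wins(self):
        results = [self._result(0.9, True, consensus_seed=1),
                   self._result(0.7, True, consensus_seed=2)]
        assert select_best_motif(results) is results[0][0]

    def test_only_significant_eligible(self):
        results = [self._result(0.99, False), self._result(0.6, True)]
        assert select_best_motif(results) is results[1][0]

    def test_no_significant_errors(self):
        with pytest.raises(NoSignificantMotifError):
            select_best_motif([self._result(0.9, False)])


class TestDiscovery:
    def test_planted_word_recovered(self, rng):
        word = "ACGTACGT"
        seqs = []
        for _ in range(60):
            bg = "".join(rng.choice(list("ACGT"), size=60))
            pos = int(rng.integers(0, 52))
            seqs.append(bg[:pos] + word + bg[pos + 8 :])
        cands = discover_motifs(seqs, widths=[8], n_per_width=5, seed=1)
        from peakscan.genomics import reverse_complement

        consensi = {c.pwm.consensus for c in cands}
        assert word in consensi or reverse_complement(word) in consensi

    def test_deterministic(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=80)) for _ in range(30)]
        a = discover_motifs(seqs, widths=[6, 7], n_per_width=3, seed=4)
        b = discover_motifs(seqs, widths=[6, 7], n_per_width=3, seed=4)
        assert [c.pwm.consensus for c in a] == [c.pwm.consensus for c in b]
        assert all(
            np.allclose(x.pwm.half_a, y.pwm.half_a) for x, y in zip(a, b)
        )

    def test_width_skipped_with_warning(self, rng):
        seqs = ["ACGTAC"] * 20
        with pytest.warns(UserWarning, match="width"):
            cands = discover_motifs(seqs, widths=[10], n_per_width=2, seed=0)
        assert cands == []

    def test_random_sequences_yield_no_significant_motif(self, rng):
        failures = 0
        for seed in range(5):
            r = np.random.default_rng(seed + 50)
            mk = lambda n: [  # noqa: E731
                "".join(r.choice(list("ACGT"), size=100)) for _ in range(n)
            ]
            train, evals = mk(60), mk(120)
            bgg, bgm = mk(120), mk(120)
            cands = discover_motifs(train, widths=[6, 8, 10], n_per_width=5, seed=seed)
            results = evaluate_candidates(cands, train, evals, bgg, bgm)
            failures += any(res.significant for _, res in results)
        assert failures <= 1  # null discoveries must be rare across seeds


class TestDualBackgroundFilter:
    def test_motif_shared_with_genomic_background_rejected(self, rng):
        """A motif equally frequent in peaks and genomic background fails."""
        word = "ACGTACGTAC"

        def with_word(n, rate):
            out = []
            for _ in range(n):
                bg = "".join(rng.choice(list("ACGT"), size=80))
                if rng.random() < rate:
                    pos = int(rng.integers(0, 70))
                    bg = bg[:pos] + word + bg[pos + 10 :]
                out.append(bg)
            return out

        train = with_word(50, 0.8)
        evals = with_word(200, 0.8)
        bg_genomic = with_word(200, 0.8)  # compositional bias shared
        bg_markov = with_word(200, 0.0)
        cand = MotifCandidate(build_pwm([word], pseudocount=0.25))
        results = evaluate_candidates([cand], train, evals, bg_genomic, bg_markov)
        (_, res), = results
        assert res.fold_markov > 1.5  # enriched vs Markov only
        assert res.fold_genomic < 1.5
        assert not res.significant


class TestBinomialOverrepresentation:
    def test_worked_example_via_scan(self):
        # library motif hits 8/10 in set A while set B rate is 0.5
        pwm = build_pwm(["ACGTACGT"])
        setA = ["ACGTACGT"] * 8 + ["TTTTCCCC"] * 2
        setB = ["ACGTACGT"] * 5 + ["TTTTCCCC"] * 5
        df = binomial_overrepresentation({"m": pwm}, setA, setB, 10.0)
        assert df.loc["m", "p_binomial"] == pytest.approx(56 / 1024)

    def test_zero_hits_in_a(self):
        pwm = build_pwm(["ACGTACGT"])
        df = binomial_overrepresentation(
            {"m": pwm}, ["TTTTTTTT"] * 5, ["ACGTACGT"] * 5, 15.9
        )
        assert df.loc["m", "p_binomial"] == 1.0

    def test_degenerate_rate_flagged(self):
        pwm = build_pwm(["ACGTACGT"])
        df = binomial_overrepresentation(
            {"m": pwm}, ["ACGTACGT"] * 3, ["TTTTTTTT"] * 5, 10.0
        )
        assert df.loc["m", "degenerate"]
        assert df.loc["m", "p_binomial"] == 0.0

    def test_bonferroni_counts_motifs_with_hits(self):
        pwms = {
            "hit1": build_pwm(["ACGTACGT"]),
            "hit2": build_pwm(["TTGGCCAA"]),
            "miss": build_pwm(["ACACACAC"]),
        }
        setA = ["ACGTACGT", "TTGGCCAA"] * 3
        setB = ["ACGTACGT", "TTGGCCAA"] * 3
        df = binomial_overrepresentation(pwms, setA, setB, 10.0)
        assert (df["bonferroni_m"] == 2).all()
        assert df.loc["hit1", "p_bonferroni"] == pytest.approx(
            min(1.0, 2 * df.loc["hit1", "p_binomial"])
        )

    @given(st.data())
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_binomial_tail_matches_enumeration(self, data):
        from scipy.stats import binom

        n = data.draw(st.integers(1, 20))
        x = data.draw(st.integers(0, n))
        p = data.draw(st.floats(0.05, 0.95))
        assert float(binom.sf(x - 1, n, p)) == pytest.approx(
            enum_binom_upper(x, n, p), abs=1e-10
        )
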