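"""PWM scanning, exact p-values, the random-region null and the Z-score."""

import numpy as np
import pytest

from chromare.io import GenomicInterval, IntervalSet, Pwm
from chromare.motifs import (
    PwmScorer,
    count_occurrences,
    extract_windows,
    motif_enrichment,
    motif_zscore,
    pvalue_from_score,
    sample_random_regions,
    scan_pwm,
)
from chromare.simulate import random_pwm, reverse_complement

from _oracles import brute_force_scan, zscore_oracle

UNIFORM = np.full(4, 0.25)


def single_base_pwm():
    # one position, all mass on A (tiny epsilon keeps log-odds finite)
    probs = np.array([[1 - 3e-9, 1e-9, 1e-9, 1e-9]])
    return Pwm("A1", probs, UNIFORM)


class TestScanning:
    def test_single_A_scores_two_bits_everywhere(self):
        pwm = single_base_pwm()
        hits = scan_pwm({"r": "AACA"}, pwm, p_threshold=0.5)
        plus = [h for h in hits if h.strand == "+"]
        assert [h.offset for h in plus] == [0, 1, 3]
        assert all(h.score == pytest.approx(2.0, abs=1e-2) for h in plus)

    def test_reverse_complement_swaps_strands(self):
        rng = np.random.default_rng(3)
        pwm = random_pwm(rng, "m", 6)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        fwd = scan_pwm({"r": seq}, pwm, 1e-2)
        rc = scan_pwm({"r": reverse_complement(seq)}, pwm, 1e-2)
        assert len(fwd) == len(rc)
        flip = {"+": "-", "-": "+"}
        assert sorted((flip[h.strand], h.score) for h in fwd) == pytest.approx(
            sorted((h.strand, h.score) for h in rc)
        )

    def test_matches_brute_force_enumeration(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=400,
                                 p=[0.3, 0.2, 0.2, 0.3]))
        regions = {"r0": seq[:200], "r1": seq[200:]}
        pwm = random_pwm(rng, "m3", 3).with_background(
            np.array([0.3, 0.2, 0.2, 0.3])
        )
        mine = scan_pwm(regions, pwm, p_threshold=0.05)
        oracle = brute_force_scan(regions, pwm, 0.05)
        assert {(h.region_id, h.offset, h.strand) for h in mine} == {
            (r, o, s) for r, o, s, _, _ in oracle
        }

    def test_windows_with_N_are_skipped(self):
        pwm = single_base_pwm()
        hits = scan_pwm({"r": "ANAA"}, pwm, p_threshold=0.5)
        assert all(h.offset != 1 for h in hits)

    def test_invalid_letter_rejected(self):
        with pytest.raises(ValueError, match="invalid sequence letter"):
            scan_pwm({"r": "ACGX"}, single_base_pwm(), 0.5)

    def test_zero_probability_pwm_rejected(self):
        pwm = Pwm("z", np.array([[1.0, 0, 0, 0]]), UNIFORM)
        with pytest.raises(ValueError, match="positive pseudocount"):
            scan_pwm({"r": "ACGT"}, pwm, 0.5)

    def test_lower_threshold_never_increases_counts(self, rng):
        pwm = random_pwm(rng, "m", 8)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        counts = [
            len(scan_pwm({"r": seq}, pwm, p)) for p in (1e-2, 1e-3, 1e-4)
        ]
        assert counts == sorted(counts, reverse=True)


class TestPvalues:
    def test_below_minimum_is_one(self, rng):
        pwm = random_pwm(rng, "m", 5)
        assert pvalue_from_score(pwm, -1e6) == 1.0

    def test_maximum_score_closed_form(self, rng):
        """p(max score) = product of background probs of the best base."""
        bg = np.array([0.3, 0.2, 0.2, 0.3])
        pwm = random_pwm(rng, "m", 6).with_background(bg)
        scorer = PwmScorer(pwm)
        best = scorer.int_scores.max(axis=1)
        expected = 1.0
        for i in range(len(pwm)):
            ties = scorer.int_scores[i] == best[i]
            expected *= bg[ties].sum()
        p = scorer.pvalue(best.sum() * scorer.granularity)
        assert p == pytest.approx(expected, rel=1e-9)

    def test_uniform_pwm_scores_zero_p_one(self):
        pwm = Pwm("u", np.full((4, 4), 0.25), UNIFORM)
        assert pvalue_from_score(pwm, 0.0) == 1.0
        hits = scan_pwm({"r": "ACGTACGT"}, pwm, p_threshold=1.0)
        assert all(h.score == 0.0 and h.pvalue == 1.0 for h in hits)

    def test_monotone_non_increasing_in_score(self, rng):
        pwm = random_pwm(rng, "m", 6)
        scorer = PwmScorer(pwm)
        ps = [scorer.pvalue(s) for s in np.linspace(-10, 12, 50)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_full_enumeration_agreement_short_motif(self, rng):
        pwm = random_pwm(rng, "m", 4).with_background(
            np.array([0.3, 0.2, 0.2, 0.3])
        )
        seq = "".join(rng.choice(list("ACGT"), size=100))
        mine = scan_pwm({"r": seq}, pwm, p_threshold=0.2)
        oracle = {(r, o, s): p for r, o, s, _, p in
                  brute_force_scan({"r": seq}, pwm, 0.2)}
        assert len(mine) == len(oracle)
        for h in mine:
            assert h.pvalue == pytest.approx(
                oracle[(h.region_id, h.offset, h.strand)], rel=1e-12
            )


class TestWindowsAndCounting:
    def test_window_extraction_width_and_truncation(self):
        genome = {"chr1": "ACGT" * 100}
        sites = IntervalSet((
            GenomicInterval("chr1", 150, 250, name="mid", summit=50),
            GenomicInterval("chr1", 1, 100, name="edge", summit=49),
        ))
        regions, truncated = extract_windows(sites, genome, 200)
        assert len(regions["mid"]) == 200
        assert len(regions["edge"]) == 150  # clipped at the chromosome start
        assert truncated == {"edge"}

    def test_window_must_be_positive_even(self):
        with pytest.raises(ValueError):
            extract_windows(IntervalSet(), {}, 0)

    def test_count_modes(self):
        from chromare.motifs import MotifHit

        hits = [MotifHit("r1", "m", o, "+", 1.0, 0.01) for o in (0, 5, 9)]
        assert count_occurrences(hits, "occurrences") == 3
        assert count_occurrences(hits, "regions_with_hit") == 1
        assert count_occurrences([], "occurrences") == 0

    def test_counts_additive_over_disjoint_region_sets(self, rng):
        pwm = random_pwm(rng, "m", 6)
        s1 = "".join(rng.choice(list("ACGT"), size=500))
        s2 = "".join(rng.choice(list("ACGT"), size=500))
        both = len(scan_pwm({"a": s1, "b": s2}, pwm, 1e-2))
        split = len(scan_pwm({"a": s1}, pwm, 1e-2)) + len(
            scan_pwm({"b": s2}, pwm, 1e-2)
        )
        assert both == split


class TestRandomRegions:
    def test_lengths_matched_one_to_one(self):
        draws = sample_random_regions({"chr1": 10_000, "chr2": 5_000},
                                      [200, 300, 150], n_draws=10, seed=1)
        assert len(draws) == 10
        for regions in draws:
            assert [e - s for _, s, e in regions] == [200, 300, 150]
            for chrom, s, e in regions:
                assert s >= 0 and e <= {"chr1": 10_000, "chr2": 5_000}[chrom]

    def test_deterministic_under_seed(self):
        a = sample_random_regions({"chr1": 10_000}, [200] * 5, 20, seed=9)
        b = sample_random_regions({"chr1": 10_000}, [200] * 5, 20, seed=9)
        assert a == b

    def test_impossible_length_rejected(self):
        with pytest.raises(ValueError, match="shortest chromosome"):
            sample_random_regions({"chr1": 100}, [200], 5, seed=0)


class TestZScore:
    def test_x_equal_mu_gives_zero(self):
        z = motif_zscore(4, [3, 4, 5, 4])
        assert z.z == 0.0

    def test_arithmetic_example(self):
        # null with mu = 4, population sigma = 2
        nulls = [2, 2, 6, 6]
        z = motif_zscore(10, nulls)
        assert (z.mu, z.sigma, z.z) == (4.0, 2.0, 3.0)

    def test_sigma_zero_flagged_not_infinite(self):
        z = motif_zscore(10, [4, 4, 4])
        assert z.z is None and not z.defined
        assert (z.x, z.mu) == (10, 4.0)

    def test_fewer_than_two_nulls_rejected(self):
        with pytest.raises(ValueError):
            motif_zscore(1, [3])

    def test_matches_statistics_module_oracle(self, rng):
        nulls = rng.poisson(7, size=100).tolist()
        x = 19
        z = motif_zscore(x, nulls)
        mu, sigma, z_oracle = zscore_oracle(x, nulls)
        assert z.mu == mu
        assert z.sigma == pytest.approx(sigma, rel=1e-12)
        assert z.z == pytest.approx(z_oracle, rel=1e-12)


class TestEnrichmentPipeline:
    def test_pipeline_is_deterministic_and_sorted(self, rng):
        genome = {"chr1": "".join(rng.choice(list("ACGT"), size=50_000))}
        sites = IntervalSet(tuple(
            GenomicInterval("chr1", i * 2000 + 100, i * 2000 + 300,
                            name=f"s{i}", summit=100)
            for i in range(10)
        ))
        pwms = [random_pwm(rng, f"p{i}", 6) for i in range(3)]
        df1 = motif_enrichment(sites, genome, pwms, n_draws=20,
                               p_threshold=1e-2, seed=5)
        df2 = motif_enrichment(sites, genome, pwms, n_draws=20,
                               p_threshold=1e-2, seed=5)
        assert df1.equals(df2)
        zs = df1["z"].dropna().tolist()
        assert zs == sorted(zs, reverse=True)
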