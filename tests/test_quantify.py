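"""Incorporation rates, profiles, exact enrichment test vs enumeration oracle."""

import numpy as np
import pytest
from scipy.stats import hypergeom

from tunnelseq.calling import BaseCall, Read
from tunnelseq.motifs import MappedRead, map_read, p53_motif
from tunnelseq.quantify import (
    compare_fractions,
    exposure_trend,
    incorporation_rate,
    position_profile,
    tally_t_site_calls,
)


def fisher_oracle(a, b, c, d):
    """Two-tail Fisher p by direct hypergeometric enumeration."""
    N, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, c1 - (c + d)), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, N, r1, c1)
    p_obs = hypergeom.pmf(a, N, r1, c1)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def make_read(seq, rel_g=None):
    calls = tuple(
        BaseCall(
            call=c,
            posterior={},
            phred_q=30.0,
            rel_G=rel_g[i] if rel_g is not None else 0.5,
        )
        for i, c in enumerate(seq)
    )
    return Read(calls=calls)


def mapped_reads(seqs, motif, rel_g_map=None):
    out = []
    for seq in seqs:
        rel_g = [rel_g_map[c] for c in seq] if rel_g_map else None
        mr = map_read(make_read(seq, rel_g), motif)
        assert mr is not None
        out.append(mr)
    return out


REL_G = {"G": 1.0, "A": 0.77, "C": 0.686, "T": 0.451, "F": 0.206, "N": 0.0}


class TestIncorporationRate:
    @pytest.mark.parametrize(
        "n_f, n_t, n_other, convention, expected_pct",
        [
            (229, 1984, 0, "exclusive", 10.3),
            (345, 1992, 0, "exclusive", 14.8),
            (120, 1651 - 120, 0, "inclusive", 7.3),
            (17, 606 - 17, 0, "inclusive", 2.8),
            (5, 974 - 5, 0, "inclusive", 0.5),
            (35, 2038 - 35, 0, "inclusive", 1.7),
            (118, 1760 - 118, 0, "inclusive", 6.7),
        ],
    )
    def test_published_count_arithmetic(self, n_f, n_t, n_other, convention, expected_pct):
        res = incorporation_rate(n_f, n_t, n_other, convention=convention)
        assert res.percent == pytest.approx(expected_pct, abs=0.05)

    def test_wilson_interval_contains_estimate(self, rng):
        for _ in range(50):
            n_f = int(rng.integers(0, 50))
            n_t = int(rng.integers(1, 200))
            res = incorporation_rate(n_f, n_t)
            assert 0.0 <= res.ci_low <= res.rate <= res.ci_high <= 1.0

    def test_exclusive_at_least_inclusive(self, rng):
        for _ in range(25):
            n_f, n_t = int(rng.integers(1, 40)), int(rng.integers(1, 200))
            n_o = int(rng.integers(0, 60))
            ex = incorporation_rate(n_f, n_t, n_o, convention="exclusive")
            inc = incorporation_rate(n_f, n_t, n_o, convention="inclusive")
            if n_o > 0:
                assert ex.rate > inc.rate
            else:
                assert ex.rate == inc.rate

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            incorporation_rate(0, 0)


class TestTallyAndProfile:
    def test_unmodified_reads_tally_all_t(self, p53):
        reads = mapped_reads(["AGACATGCCCAGACATGCCC"] * 10, p53)
        per_site, pooled = tally_t_site_calls(reads, p53)
        assert pooled == (0, 20, 0)
        assert per_site[6] == (0, 10, 0) and per_site[16] == (0, 10, 0)

    def test_substituted_reads_tally_all_f(self, p53):
        reads = mapped_reads(["AGACAFGCCCAGACAFGCCC"] * 10, p53)
        _, pooled = tally_t_site_calls(reads, p53)
        assert pooled == (20, 0, 0)

    def test_simulation_tally_matches_ground_truth(self, p53):
        rng = np.random.default_rng(9)
        seqs = []
        n_f = n_t = 0
        for _ in range(500):
            seq = list(p53.sequence)
            for pos in (5, 15):
                if rng.uniform() < 0.10:
                    seq[pos] = "F"
                    n_f += 1
                else:
                    n_t += 1
            seqs.append("".join(seq))
        _, pooled = tally_t_site_calls(mapped_reads(seqs, p53), p53)
        assert pooled == (n_f, n_t, 0)

    def test_profile_masses_at_t_and_f_relative_g(self, p53):
        for seq, expected in (
            ("AGACATGCCCAGACATGCCC", 0.451),
            ("AGACAFGCCCAGACAFGCCC", 0.206),
        ):
            profile = position_profile(
                mapped_reads([seq] * 100, p53, rel_g_map=REL_G), p53
            )
            vals = profile.values[6]
            assert len(vals) == 100
            assert all(v == pytest.approx(expected) for v in vals)
        # histogram row sums equal per-position counts
        assert (profile.histogram.sum(axis=1) == 100).all()

    def test_empty_profile_valid(self, p53):
        profile = position_profile([], p53)
        assert profile.n_observations == 0
        assert profile.histogram.sum() == 0


class TestCompareFractions:
    def test_bound_vs_unbound_direction(self):
        res = compare_fractions(35, 2038 - 35, 118, 1760 - 118)
        assert res.odds_ratio < 1
        assert res.p_two_sided < 0.001
        assert res.p_two_sided == pytest.approx(
            fisher_oracle(35, 2003, 118, 1642), rel=1e-9
        )

    def test_identical_groups_null(self):
        res = compare_fractions(10, 90, 10, 90)
        assert res.odds_ratio == 1.0
        assert res.p_two_sided == 1.0

    def test_extreme_table_two_tail_mass(self):
        res = compare_fractions(0, 10, 10, 0)
        assert res.p_two_sided == pytest.approx(fisher_oracle(0, 10, 10, 0), rel=1e-9)

    def test_symmetric_under_group_swap(self, rng):
        for _ in range(20):
            a, b, c, d = (int(x) for x in rng.integers(0, 25, size=4))
            if a + b == 0 or c + d == 0:
                continue
            r1 = compare_fractions(a, b, c, d)
            r2 = compare_fractions(c, d, a, b)
            assert r1.p_two_sided == pytest.approx(r2.p_two_sided, rel=1e-12)

    def test_matches_enumeration_oracle_small_margins(self):
        import warnings

        for r1 in range(1, 13):
            for r2 in range(1, 13):
                for a in range(r1 + 1):
                    for c in range(r2 + 1):
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            res = compare_fractions(a, r1 - a, c, r2 - c)
                        if a + c == 0 or (r1 - a) + (r2 - c) == 0:
                            assert res.p_two_sided == 1.0
                            continue
                        expected = fisher_oracle(a, r1 - a, c, r2 - c)
                        assert res.p_two_sided == pytest.approx(expected, rel=1e-7)

    def test_degenerate_margin_warns(self):
        with pytest.warns(UserWarning):
            res = compare_fractions(0, 10, 0, 12)
        assert res.p_two_sided == 1.0


class TestExposureTrend:
    def _res(self, n_f, n_t):
        return incorporation_rate(n_f, n_t)

    def test_published_trend_monotone(self):
        df = exposure_trend(
            {"F1": self._res(229, 1984), "F5": self._res(345, 1992)}, order=("F1", "F5")
        )
        assert list(df["condition"]) == ["F1", "F5"]
        assert df.attrs["monotone_increasing"]

    def test_non_monotone_flagged(self):
        df = exposure_trend(
            {"A": self._res(20, 80), "B": self._res(10, 90)}, order=("A", "B")
        )
        assert not df.attrs["monotone_increasing"]

    def test_single_entry(self):
        df = exposure_trend({"P": self._res(1, 99)})
        assert len(df) == 1 and df.attrs["monotone_increasing"]

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            exposure_trend([("A", self._res(1, 9)), ("A", self._res(2, 8))])


class TestParameterRecovery:
    def test_pipeline_recovers_substitution_rate(self):
        """End-to-end bias and CI coverage over 20 simulated datasets."""
        from tunnelseq.calling import BaseCaller
        from tunnelseq.detection import EventDetector, LevelSegmenter
        from tunnelseq.motifs import map_read as _map
        from tunnelseq.simulate import SimulationConfig, simulate_dataset

        motif = p53_motif()
        caller = BaseCaller().fit()
        biases, covered = [], 0
        cases = [(p, s) for p in (0.02, 0.05, 0.10, 0.15) for s in range(5)]
        for p, s in cases:
            cfg = SimulationConfig(
                ftd_substitution_prob=p,
                n_events=1000,
                read_truncation=(5, 20),
                seed=1000 * s + int(p * 1000),
            )
            trace, truth = simulate_dataset(cfg)
            events = EventDetector().fit_predict(trace)
            levels = LevelSegmenter().transform(trace, events)
            reads = [caller.call(lv, source_event=i) for i, lv in enumerate(levels) if lv]
            mapped = [
                m for m in (_map(r, motif) for r in reads if len(r) <= len(motif)) if m
            ]
            _, pooled = tally_t_site_calls(mapped, motif)
            res = incorporation_rate(*pooled)
            biases.append(res.rate - p)
            covered += res.ci_low <= p <= res.ci_high
        assert abs(np.mean(biases)) < 0.01
        assert covered >= 17
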