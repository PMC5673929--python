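"""One-sample KS test, BH adjustment and per-set statistics."""

import numpy as np
import pytest

from chemrich.enrichment import (
    EnrichmentRow,
    bh_fdr,
    ks_statistic,
    ks_uniform_test,
    set_statistics,
)
from chemrich.ontology import ChemSet


class Rec:
    def __init__(self, cid, p, fc):
        self.compound_id, self.effect_p, self.fold_change = cid, p, fc


class TestKSUniform:
    def test_single_point_at_half(self):
        # for n=1 the statistic is max(x, 1-x) >= 0.5 always, so P(D >= 0.5) = 1
        res = ks_uniform_test([0.5])
        assert res.D == pytest.approx(0.5)
        assert res.p_value == pytest.approx(1.0)
        assert res.method == "exact"

    def test_equioscillating_sample_minimizes_d(self):
        # {(2i-1)/(2n)} for n=4: empirical CDF oscillates +-1/8 around uniform
        sample = [(2 * i - 1) / 8 for i in range(1, 5)]
        assert ks_statistic(np.array(sample)) == pytest.approx(1 / 8)

    def test_extreme_sample_near_one(self):
        res = ks_uniform_test([1e-12] * 5)
        assert res.D == pytest.approx(1.0, abs=1e-9)
        assert res.p_value < 1e-10

    def test_errors(self):
        with pytest.raises(ValueError):
            ks_uniform_test([])
        with pytest.raises(ValueError):
            ks_uniform_test([0.5, 1.5])
        with pytest.raises(ValueError):
            ks_uniform_test([-0.1])

    def test_ties_warn_but_stay_exact(self):
        with pytest.warns(UserWarning, match="ties"):
            res = ks_uniform_test([0.01, 0.01, 0.5])
        assert res.method == "exact"

    def test_asymptotic_for_large_n(self, rng):
        res = ks_uniform_test(rng.uniform(size=150))
        assert res.method == "asymptotic"

    @pytest.mark.parametrize("n", [2, 3, 5])
    def test_exact_matches_monte_carlo(self, n, rng):
        """Exact small-sample p-values agree with simulation (quick check;
        the acceptance suite runs the full 10^6-sample version)."""
        n_sim = 200_000
        sims = np.sort(rng.uniform(size=(n_sim, n)), axis=1)
        i = np.arange(1, n + 1)
        d_sim = np.maximum(i / n - sims, sims - (i - 1) / n).max(axis=1)
        for _ in range(3):
            res = ks_uniform_test(rng.uniform(size=n))
            mc = float((d_sim >= res.D - 1e-12).mean())
            se = np.sqrt(mc * (1 - mc) / n_sim) + 1e-12
            assert abs(res.p_value - mc) < max(3 * se, 5e-4)


class TestBHFdr:
    def test_rank_one_times_m(self):
        out = bh_fdr({"top": 2.2e-20, "other": 0.5}, m=50)
        assert out["top"] == pytest.approx(1.1e-18)

    def test_all_equal_collapse(self):
        out = bh_fdr({f"s{i}": 0.01 for i in range(10)})
        assert all(v == pytest.approx(0.01) for v in out.values())

    def test_single_value_identity(self):
        assert bh_fdr({"only": 0.2}, m=1)["only"] == pytest.approx(0.2)

    def test_monotone_and_order_invariant(self, rng):
        p = rng.uniform(size=30)
        labels = [f"s{i}" for i in range(30)]
        out1 = bh_fdr(dict(zip(labels, p)))
        out2 = bh_fdr(dict(zip(reversed(labels), reversed(p.tolist()))))
        assert out1 == out2
        ranked = sorted(labels, key=lambda l: p[labels.index(l)])
        adj = [out1[l] for l in ranked]
        assert adj == sorted(adj)
        for l in labels:
            assert out1[l] >= p[labels.index(l)]

    def test_cross_check_against_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=25)
        labels = [f"s{i}" for i in range(25)]
        ours = bh_fdr(dict(zip(labels, p)))
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        for l, r in zip(labels, ref):
            assert ours[l] == pytest.approx(r, abs=1e-12)

    def test_m_smaller_than_input_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr({"a": 0.1, "b": 0.2}, m=1)


class TestSetStatistics:
    def test_constructed_direction_counts(self):
        records = [Rec("a", 0.01, 2.0), Rec("b", 0.02, 0.5), Rec("c", 0.6, 3.0)]
        row = set_statistics(ChemSet("test", ["a", "b", "c"]), records)
        assert (row.n_altered, row.n_increased, row.n_decreased) == (2, 1, 1)
        assert row.size == 3

    def test_no_altered_members(self):
        with pytest.warns(UserWarning):
            row = set_statistics(
                ChemSet("flat", ["a", "b", "c"]),
                [Rec("a", 0.5, 2.0), Rec("b", 0.5, 0.5), Rec("c", 0.5, 1.0)],
            )
        assert row.n_altered == 0

    def test_fold_change_exactly_one_counts_neither_direction(self):
        records = [Rec("a", 0.01, 1.0), Rec("b", 0.02, 2.0), Rec("c", 0.03, 0.5)]
        row = set_statistics(ChemSet("s", ["a", "b", "c"]), records)
        assert row.n_altered == 3
        assert row.n_increased == 1 and row.n_decreased == 1
        assert row.n_flat_fold_change == 1
        assert row.n_altered == row.n_increased + row.n_decreased + row.n_flat_fold_change

    def test_missing_member_is_consistency_error(self):
        with pytest.raises(ValueError, match="missing"):
            set_statistics(ChemSet("s", ["ghost"]), [Rec("a", 0.5, 1.0)])


def test_type_one_error_calibration(rng):
    """Null sets (members ~ Uniform) are rejected at the nominal 5% rate.

    Quick version (200 studies x 20 sets); the acceptance suite runs the
    full 1000-study calibration.
    """
    rejections = total = 0
    for _ in range(200):
        for _ in range(20):
            size = int(rng.integers(3, 21))
            res = ks_uniform_test(rng.uniform(size=size))
            rejections += res.p_value < 0.05
            total += 1
    rate = rejections / total
    assert 0.035 < rate < 0.065
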