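"""Reference-gene stability statistics and rank aggregation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from qpcrkit import (
    aggregate_ranking,
    bestkeeper,
    ct_matrix,
    cv_ranking,
    deltact_stability,
    genorm_m,
    genorm_v,
    normfinder,
    stability_report,
)
from qpcrkit.stability import _rank_ascending, observation_groups


def _matrix(data: dict[str, list[float]]) -> pd.DataFrame:
    return pd.DataFrame(data).T


class TestCv:
    def test_constant_gene_zero(self):
        cv = cv_ranking(_matrix({"g": [25.0, 25.0, 25.0]}))
        assert cv["g"] == 0.0

    def test_hand_value(self):
        # SD = sqrt(2), mean 21 -> CV 6.7343%
        cv = cv_ranking(_matrix({"g": [20.0, 22.0]}))
        assert cv["g"] == pytest.approx(100 * math.sqrt(2) / 21, abs=1e-4)
        assert cv["g"] == pytest.approx(6.7343, abs=1e-3)

    def test_ordering(self):
        cv = cv_ranking(_matrix({"a": [25.0, 25.6], "b": [25.0, 25.4]}))
        ranks = _rank_ascending(cv)
        assert ranks["b"] == 1 and ranks["a"] == 2

    def test_short_gene_excluded(self):
        m = _matrix({"a": [25.0, np.nan], "b": [25.0, 25.4]})
        cv = cv_ranking(m)
        assert "a" not in cv.index


class TestDeltaCt:
    def test_constant_offset_zero(self):
        m = _matrix({"g": [24.0, 25.0, 26.0], "h": [27.0, 28.0, 29.0]})
        stat = deltact_stability(m)
        assert stat["g"] == pytest.approx(0.0)
        assert stat["h"] == pytest.approx(0.0)

    def test_identical_genes_all_zero(self):
        m = _matrix({g: [24.0, 25.5, 23.8] for g in "abcd"})
        assert (deltact_stability(m) == 0).all()

    def test_matches_explicit_loop_oracle(self):
        rng = np.random.default_rng(17)
        genes = [f"g{i}" for i in range(5)]
        m = _matrix({g: list(25 + rng.normal(0, 1, 8)) for g in genes})
        stat = deltact_stability(m)
        for g in genes:
            sds = []
            for h in genes:
                if h == g:
                    continue
                diffs = [m.loc[g, c] - m.loc[h, c] for c in m.columns]
                mean = sum(diffs) / len(diffs)
                sd = math.sqrt(sum((d - mean) ** 2 for d in diffs) / (len(diffs) - 1))
                sds.append(sd)
            assert stat[g] == pytest.approx(sum(sds) / len(sds), abs=1e-12)

    def test_noisy_gene_statistic_scale(self):
        """A gene = partner + noise has pairwise SD near the noise SD."""
        rng = np.random.default_rng(3)
        base = 25 + rng.normal(0, 0.1, 2000)
        noise_sd = 1.0
        m = _matrix(
            {
                "g1": list(base),
                "g2": list(base + 3.0),
                "g3": list(base + rng.normal(0, noise_sd, 2000)),
            }
        )
        stat = deltact_stability(m)
        assert stat["g3"] == pytest.approx(noise_sd, rel=0.1)
        assert stat["g1"] < stat["g3"]


class TestBestKeeper:
    def test_perfectly_tracking_gene_r_one(self):
        rng = np.random.default_rng(9)
        base = 25 + rng.normal(0, 1, 6)
        m = _matrix({"a": list(base), "b": list(base + 1), "c": list(base - 1)})
        bk = bestkeeper(m)
        assert bk.loc["a", "bestkeeper_r"] == pytest.approx(1.0)

    def test_zero_variance_gene(self):
        rng = np.random.default_rng(9)
        m = _matrix(
            {"flat": [25.0] * 5, "x": list(25 + rng.normal(0, 1, 5)),
             "y": list(25 + rng.normal(0, 1, 5))}
        )
        bk = bestkeeper(m)
        assert bk.loc["flat", "bestkeeper_sd"] == 0.0
        assert math.isnan(bk.loc["flat", "bestkeeper_r"])
        assert _rank_ascending(bk["bestkeeper_sd"])["flat"] == 1

    def test_matches_manual_spreadsheet_computation(self):
        m = _matrix(
            {
                "a": [24.0, 25.0, 26.0, 25.0],
                "b": [23.0, 24.5, 25.5, 24.0],
                "c": [26.0, 26.5, 27.5, 27.0],
            }
        )
        bk = bestkeeper(m)
        for gene in "abc":
            vals = np.array(m.loc[gene])
            assert bk.loc[gene, "bestkeeper_sd"] == pytest.approx(
                vals.std(ddof=1), abs=1e-12
            )
            assert bk.loc[gene, "bestkeeper_cv"] == pytest.approx(
                100 * vals.std(ddof=1) / vals.mean(), abs=1e-12
            )
        index = np.exp(np.mean(np.log(m.values), axis=0))
        r_manual = np.corrcoef(m.loc["a"], index)[0, 1]
        assert bk.loc["a", "bestkeeper_r"] == pytest.approx(r_manual, abs=1e-12)

    def test_needs_three_samples(self):
        with pytest.raises(ValueError):
            bestkeeper(_matrix({"a": [25.0, 26.0], "b": [25.0, 26.0]}))


class TestNormFinder:
    def test_zero_residual_gene(self):
        rng = np.random.default_rng(2)
        shifts = rng.normal(0, 1, 6)
        # every gene moves with the per-sample mean -> residuals constant
        m = _matrix({g: list(25 + shifts) for g in "abc"})
        rho = normfinder(m)
        assert (rho.abs() < 1e-12).all()

    def test_group_shifted_gene_ranked_last(self):
        G = 6
        data = {f"g{i}": [25.0] * 8 for i in range(G - 1)}
        data["shifted"] = [25.0] * 4 + [26.0] * 4
        m = _matrix(data)
        groups = {c: ("k1" if int(str(c)) < 4 else "k2") for c in m.columns}
        rho = normfinder(m, groups=groups)
        assert rho.idxmax() == "shifted"
        # residual group deviation is +-(1 - 1/G)/2 for the shifted gene
        assert rho["shifted"] == pytest.approx((1 - 1 / G) / 2, abs=1e-12)

    def test_sample_centering_invariance(self):
        rng = np.random.default_rng(4)
        m = _matrix({g: list(25 + rng.normal(0, 0.5, 6)) for g in "abcd"})
        shifted = m.copy()
        shifted.iloc[:, 2] += 3.0  # one sample loaded differently
        assert np.allclose(normfinder(m).values, normfinder(shifted).values)

    def test_singleton_group_rejected(self):
        m = _matrix({g: [25.0, 25.0, 25.0] for g in "abc"})
        groups = {m.columns[0]: "k1", m.columns[1]: "k1", m.columns[2]: "k2"}
        with pytest.raises(ValueError, match="k2"):
            normfinder(m, groups=groups)


class TestGeNorm:
    def test_constant_ratio_pair_zero_v(self):
        rng = np.random.default_rng(6)
        base = 25 + rng.normal(0, 1, 6)
        m = _matrix(
            {"a": list(base), "b": list(base + 2), "c": list(25 + rng.normal(0, 1, 6))}
        )
        m_values, order = genorm_m(m)
        # a and b keep a constant ratio: they survive to the final two
        assert set(order[:2]) == {"a", "b"}
        assert m_values["a"] == m_values["b"]

    def test_duplicate_gene_survives(self):
        rng = np.random.default_rng(12)
        data = {f"g{i}": list(25 + rng.normal(0, 0.5, 8)) for i in range(4)}
        data["dup"] = data["g0"]
        _, order = genorm_m(_matrix(data))
        assert set(order[:2]) == {"g0", "dup"}

    def test_initial_m_equals_deltact_at_base_two(self):
        """log2 quantity ratios reduce to Ct differences when base = 2."""
        rng = np.random.default_rng(19)
        m = _matrix({f"g{i}": list(25 + rng.normal(0, 0.7, 10)) for i in range(5)})
        from qpcrkit.stability import _genorm_m_values, _quantities

        genorm_initial = _genorm_m_values(_quantities(m, None))
        dct = deltact_stability(m)
        assert np.allclose(genorm_initial.values, dct[genorm_initial.index].values,
                           atol=1e-10)

    def test_identical_genes_v_zero_optimal_two(self):
        m = _matrix({g: [24.0, 25.0, 26.0, 25.5] for g in "abcd"})
        _, order = genorm_m(m)
        series = genorm_v(m, order)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in series.v)
        assert series.optimal_n == 2

    def test_unstable_gene_spikes_last_v(self):
        rng = np.random.default_rng(23)
        data = {f"g{i}": list(25 + rng.normal(0, 0.05, 12)) for i in range(5)}
        data["wild"] = list(25 + rng.normal(0, 3.0, 12))
        m = _matrix(data)
        _, order = genorm_m(m)
        assert order[-1] == "wild"
        series = genorm_v(m, order)
        assert series.v[-1] > 2 * series.v[-2]

    def test_matches_explicit_loop_oracle(self):
        rng = np.random.default_rng(31)
        genes = [f"g{i}" for i in range(4)]
        m = _matrix({g: list(25 + rng.normal(0, 0.3, 6)) for g in genes})
        _, order = genorm_m(m)
        series = genorm_v(m, order)
        # explicit-loop oracle for V_n
        q = {g: [2.0 ** (min(m.loc[g]) - ct) for ct in m.loc[g]] for g in m.index}
        for n_idx, n in enumerate(range(2, len(genes))):
            top_n = order[:n]
            top_n1 = order[: n + 1]
            logs = []
            for i in range(m.shape[1]):
                nf_n = np.prod([q[g][i] for g in top_n]) ** (1 / n)
                nf_n1 = np.prod([q[g][i] for g in top_n1]) ** (1 / (n + 1))
                logs.append(math.log2(nf_n / nf_n1))
            mean = sum(logs) / len(logs)
            sd = math.sqrt(sum((x - mean) ** 2 for x in logs) / (len(logs) - 1))
            assert series.v[n_idx] == pytest.approx(sd, abs=1e-10)


class TestAggregate:
    def test_unanimous_rank_one(self):
        ranks = {m: pd.Series({"g": 1.0, "h": 2.0}) for m in ("a", "b", "c", "d")}
        out = aggregate_ranking(ranks)
        assert out.loc["g", "aggregate_score"] == pytest.approx(1.0)
        assert out.loc["g", "final_rank"] == 1

    def test_geometric_mean_of_ranks(self):
        ranks = {
            "m1": pd.Series({"g": 1.0, "h": 2.0}),
            "m2": pd.Series({"g": 2.0, "h": 1.0}),
            "m3": pd.Series({"g": 4.0, "h": 3.0}),
            "m4": pd.Series({"g": 8.0, "h": 5.0}),
        }
        out = aggregate_ranking(ranks)
        assert out.loc["g", "aggregate_score"] == pytest.approx(64 ** 0.25)
        assert out.loc["g", "aggregate_score"] == pytest.approx(2.8284, abs=1e-4)

    def test_symmetric_swap_broken_by_cv(self):
        ranks = {
            "m1": pd.Series({"g": 1.0, "h": 2.0}),
            "m2": pd.Series({"g": 2.0, "h": 1.0}),
        }
        out = aggregate_ranking(ranks, cv_pct=pd.Series({"g": 1.2, "h": 0.8}))
        assert out.loc["h", "final_rank"] == 1
        assert out.loc["g", "final_rank"] == 2

    def test_missing_gene_rejected(self):
        ranks = {
            "m1": pd.Series({"g": 1.0, "h": 2.0}),
            "m2": pd.Series({"g": 1.0}),
        }
        with pytest.raises(ValueError):
            aggregate_ranking(ranks)

    def test_method_order_invariant(self):
        ranks = {
            "m1": pd.Series({"g": 1.0, "h": 2.0, "k": 3.0}),
            "m2": pd.Series({"g": 3.0, "h": 1.0, "k": 2.0}),
            "m3": pd.Series({"g": 2.0, "h": 3.0, "k": 1.0}),
        }
        a = aggregate_ranking(ranks)
        b = aggregate_ranking(dict(reversed(list(ranks.items()))))
        pd.testing.assert_series_equal(a["aggregate_score"], b["aggregate_score"])


class TestReport:
    def test_copies_table_all_tied(self, copies_table):
        report = stability_report(copies_table)
        t = report.table
        assert np.allclose(t["deltact_sd"], 0.0)
        assert np.allclose(t["genorm_m"], 0.0, atol=1e-12)
        assert np.allclose(t["normfinder_rho"], 0.0, atol=1e-12)
        assert report.v_series.optimal_n == 2

    def test_gene_order_invariance(self, stability_table):
        report_a = stability_report(stability_table, groups=True)
        shuffled = stability_table.sort_values("gene", ascending=False).reset_index(
            drop=True
        )
        report_b = stability_report(shuffled, groups=True)
        pd.testing.assert_frame_equal(
            report_a.table.sort_index(), report_b.table.sort_index()
        )

    def test_planted_gene_bottom_ranked_by_every_method(self, stability_table):
        report = stability_report(stability_table, groups=True)
        t = report.table
        n = len(t)
        for col in ("rank_cv", "rank_deltact", "rank_bestkeeper",
                    "rank_normfinder", "rank_genorm"):
            assert t.loc["planted", col] == n, col
        assert t.loc["planted", "final_rank"] == n

    def test_observation_groups(self, stability_table):
        groups = observation_groups(stability_table)
        assert set(groups.values()) == {"A", "B"}
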