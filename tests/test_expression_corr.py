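"""DEG threshold semantics, exact Spearman permutation p-values, pairwise
correlation matrices, and copy-number-versus-expression correlation."""

from itertools import permutations
from math import factorial

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clusterhop.expression_corr import (
    call_degs,
    copy_expression_correlation,
    correlation_matrix,
    correlations_to_frame,
    degs_to_frame,
    spearman_pair,
)
from clusterhop.sim import simulate_expression

RES = {"R1", "R2", "R3"}
SENS = {"S1", "S2", "S3", "S4"}


def expr_frame(rows):
    """rows: {gene: {strain: lfc}} over RES|SENS."""
    return pd.DataFrame(rows).T[sorted(RES) + sorted(SENS)]


class TestCallDegs:
    def test_threshold_is_inclusive_at_exactly_one(self):
        rows = {
            "at": {**{s: 1.0 for s in RES}, **{s: 0.0 for s in SENS}},
            "below": {**{s: 0.999 for s in RES}, **{s: 0.0 for s in SENS}},
        }
        calls = {c.gene: c for c in call_degs(expr_frame(rows), RES, SENS, "cond")}
        assert calls["at"].group_consistent and calls["at"].direction == "over"
        assert not calls["below"].group_consistent
        assert calls["below"].status["R1"] == "ns"

    def test_under_direction_symmetric(self):
        rows = {"g": {**{s: -1.2 for s in RES}, **{s: 0.1 for s in SENS}}}
        (c,) = call_degs(expr_frame(rows), RES, SENS, "cond")
        assert c.direction == "under"

    def test_one_discordant_resistant_breaks_consistency(self):
        rows = {"g": {"R1": 1.5, "R2": 1.5, "R3": 0.5, **{s: 0.0 for s in SENS}}}
        (c,) = call_degs(expr_frame(rows), RES, SENS, "cond")
        assert not c.group_consistent and c.direction is None

    def test_max_one_sensitive_concordant(self):
        base = {s: 1.5 for s in RES}
        rows = {
            "ok": {**base, "S1": 1.5, "S2": 0.0, "S3": 0.0, "S4": 0.0},
            "bad": {**base, "S1": 1.5, "S2": 1.5, "S3": 0.0, "S4": 0.0},
        }
        calls = {c.gene: c for c in call_degs(expr_frame(rows), RES, SENS, "cond")}
        assert calls["ok"].group_consistent
        assert not calls["bad"].group_consistent

    def test_missing_strain_rejected(self):
        rows = {"g": {s: 0.0 for s in RES | SENS}}
        with pytest.raises(ValueError):
            call_degs(expr_frame(rows), RES | {"R9"}, SENS, "cond")

    def test_frame_export_one_row_per_gene_strain(self):
        rows = {"g": {**{s: 1.5 for s in RES}, **{s: 0.0 for s in SENS}}}
        df = degs_to_frame(call_degs(expr_frame(rows), RES, SENS, "cond"))
        assert len(df) == 7
        assert set(df.columns) >= {"gene", "strain", "log2fc", "status", "direction"}


class TestSpearmanPair:
    def test_perfect_monotone_extremes(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        rho, p = spearman_pair(x, [v**3 for v in x])
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / factorial(5))  # both perfect orderings
        rho, _ = spearman_pair(x, [-v for v in x])
        assert rho == pytest.approx(-1.0)

    def test_rho_matches_scipy_with_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = np.round(rng.normal(size=10), 1)
            y = np.round(rng.normal(size=10), 1)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, _ = spearman_pair(x, y)
            assert rho == pytest.approx(stats.spearmanr(x, y).statistic, abs=1e-12)

    def test_exact_p_equals_permutation_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(4, 7))
            x = rng.normal(size=n)
            y = np.round(rng.normal(size=n), 1)  # ties in one vector
            if np.ptp(y) == 0:
                continue
            rho, p = spearman_pair(x, y)
            rx, ry = stats.rankdata(x), stats.rankdata(y)
            obs = abs(np.corrcoef(rx, ry)[0, 1])
            count = sum(
                abs(np.corrcoef(rx, perm)[0, 1]) >= obs - 1e-12
                for perm in permutations(ry)
            )
            assert p == pytest.approx(count / factorial(n), abs=1e-12)

    def test_t_approximation_matches_closed_form(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=30), rng.normal(size=30)
        rho, p = spearman_pair(x, y)
        t = rho * np.sqrt(28 / (1 - rho**2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), df=28))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            spearman_pair([1, 2, 3], [1, 2, 3])  # too few
        with pytest.raises(ValueError):
            spearman_pair([1, 1, 1, 1], [1, 2, 3, 4])  # zero variance
        with pytest.raises(ValueError):
            spearman_pair([1, 2, np.nan, 4], [1, 2, 3, 4])  # NaN not allowed here


class TestCorrelationMatrix:
    def test_planted_block_is_the_significant_set(self):
        genes = [f"g{i}" for i in range(8)]
        strains = [f"s{i}" for i in range(16)]
        groups = {s: "sensitive" for s in strains}
        mat = simulate_expression(
            genes, strains, groups,
            coexpr_blocks=[(["g0", "g1", "g2"], +1)], noise_sd=0.15, seed=11,
        )
        results = correlation_matrix(mat, genes)
        sig = {frozenset((r.gene_a, r.gene_b)) for r in results if r.significant}
        expected = {
            frozenset(p) for p in (("g0", "g1"), ("g0", "g2"), ("g1", "g2"))
        }
        assert expected <= sig
        # no pair outside the block sneaks in
        block = {"g0", "g1", "g2"}
        assert all(set(s) <= block for s in sig)
        assert len(results) == 8 * 7 // 2

    def test_pairwise_complete_and_undefined_exclusion(self):
        expr = pd.DataFrame(
            {
                f"s{i}": [float(i), float(i) + 0.1, 5.0, np.nan]
                for i in range(6)
            },
            index=["a", "b", "const", "gap"],
        )
        expr.loc["gap", ["s0", "s1", "s2"]] = [1.0, 2.0, 3.0]  # only 3 complete
        results = {(r.gene_a, r.gene_b): r for r in correlation_matrix(expr, ["a", "b", "const", "gap"])}
        assert results[("a", "b")].rho == pytest.approx(1.0)
        assert np.isnan(results[("a", "const")].rho)  # zero variance
        assert np.isnan(results[("a", "gap")].rho)  # < 4 complete obs
        assert not results[("a", "const")].significant
        df = correlations_to_frame(results.values())
        assert len(df) == 6

    def test_single_gene_rejected(self):
        expr = pd.DataFrame({"s1": [1.0]}, index=["a"])
        with pytest.raises(ValueError):
            correlation_matrix(expr, ["a"])


class TestCopyExpressionCorrelation:
    def test_dosage_driven_gene_detected_constant_gene_undefined(self):
        strains = [f"s{i}" for i in range(12)]
        rng = np.random.default_rng(5)
        copies = rng.choice([1.0, 2.0, 3.0], size=12)
        copy_numbers = pd.DataFrame(
            {"dosage": copies, "flat": np.ones(12), "indep": copies}, index=strains
        ).T
        expr = pd.DataFrame(
            {
                "dosage": copies + rng.normal(0, 0.05, 12),
                "flat": rng.normal(0, 1, 12),
                "indep": rng.normal(0, 1, 12),
            },
            index=strains,
        ).T
        results = {r.gene_a: r for r in copy_expression_correlation(copy_numbers, expr, ["dosage", "flat", "indep"])}
        assert results["dosage"].significant and results["dosage"].rho > 0.9
        assert np.isnan(results["flat"].rho)  # constant copy vector undefined
        assert not results["indep"].significant

    def test_missing_gene_rejected(self):
        strains = [f"s{i}" for i in range(5)]
        cn = pd.DataFrame({s: [1.0] for s in strains}, index=["g"])
        ex = pd.DataFrame({s: [1.0] for s in strains}, index=["g"])
        with pytest.raises(ValueError):
            copy_expression_correlation(cn, ex, ["g", "absent"])

    def test_too_few_shared_strains_rejected(self):
        cn = pd.DataFrame({"s1": [1.0], "s2": [1.0]}, index=["g"])
        ex = pd.DataFrame({"s1": [1.0], "s2": [1.0], "s3": [1.0]}, index=["g"])
        with pytest.raises(ValueError):
            copy_expression_correlation(cn, ex, ["g"])
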