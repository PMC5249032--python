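"""Exact NB test, dispersion estimation, logFC arithmetic, BH-FDR, calls."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom

from srnakit.de import (
    CountMatrix,
    bh_fdr,
    call_de,
    estimate_dispersion,
    exact_test,
    log_fold_change,
    run_de,
)

COND = {"c1": "control", "c2": "control", "s1": "water_stress", "s2": "water_stress"}


class TestLogFoldChange:
    @pytest.mark.parametrize(
        "control,stress,expected",
        [
            # reported per-library RPTM of strongly regulated families
            ((4192, 4134), (157, 133), -4.84),
            ((209, 207), (1459, 1281), 2.71),
            ((104, 108), (34, 30), -1.73),
            ((254, 174), (961, 917), 2.12),
            ((1357, 1574), (5426, 5396), 1.9),
        ],
    )
    def test_worked_examples(self, control, stress, expected):
        assert log_fold_change(list(control), list(stress)) == pytest.approx(
            expected, abs=0.05
        )

    def test_equal_abundance_gives_zero(self):
        assert log_fold_change([100, 200], [150, 150]) == 0.0

    def test_antisymmetry(self):
        a = log_fold_change([120, 90], [400, 350])
        b = log_fold_change([400, 350], [120, 90])
        assert a == pytest.approx(-b)

    def test_pseudocount_only_when_zero(self):
        assert log_fold_change([70, 57], [0, 0]) == pytest.approx(
            np.log2(0.5 / 127.5)
        )
        assert np.isnan(log_fold_change([0, 0], [0, 0]))
        with pytest.raises(ValueError):
            log_fold_change([], [1])


class TestDispersion:
    def test_poisson_counts_near_zero(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(
            {c: rng.poisson(500, size=60) for c in COND}, index=range(60)
        )
        assert estimate_dispersion(CountMatrix(counts, COND)) < 0.01

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(3)
        r = 1 / 0.2
        counts = pd.DataFrame(
            {c: rng.negative_binomial(r, r / (r + 500), size=50) for c in COND},
            index=range(50),
        )
        est = estimate_dispersion(CountMatrix(counts, COND))
        assert 0.1 <= est <= 0.4

    def test_identical_replicates_give_zero(self):
        col = np.arange(1, 41) * 10
        counts = pd.DataFrame({c: col for c in COND}, index=range(40))
        assert estimate_dispersion(CountMatrix(counts, COND)) == 0.0

    def test_no_replication_raises(self):
        counts = pd.DataFrame({"c1": [1, 2], "s1": [3, 4]}, index=["a", "b"])
        cm = CountMatrix(counts, {"c1": "control", "s1": "water_stress"})
        with pytest.raises(ValueError, match="dispersion"):
            estimate_dispersion(cm)


class TestExactTest:
    def test_zero_dispersion_is_binomial(self):
        """At dispersion 0 the conditional law is Binomial(t, n1/(n1+n2));
        compared against an independent tail computation."""
        ya, yb = (10, 12), (30, 28)
        p = exact_test(list(ya), list(yb), 0.0)
        t = sum(ya) + sum(yb)
        probs = binom.pmf(np.arange(t + 1), t, 0.5)
        expected = probs[probs <= probs[sum(ya)] + 1e-12].sum()
        assert p == pytest.approx(expected, rel=1e-9)

    def test_small_dispersion_converges_to_binomial(self):
        p0 = exact_test([10, 12], [30, 28], 0.0)
        p_eps = exact_test([10, 12], [30, 28], 1e-7)
        assert p_eps == pytest.approx(p0, rel=1e-3)

    def test_symmetric_counts_give_one(self):
        assert exact_test([50, 60], [60, 50], 0.1) == 1.0

    def test_label_swap_invariance(self):
        a = exact_test([10, 20], [200, 180], 0.05)
        b = exact_test([200, 180], [10, 20], 0.05)
        assert a == pytest.approx(b)

    def test_all_zero_gives_one(self):
        assert exact_test([0, 0], [0, 0], 0.1) == 1.0

    def test_negative_dispersion_raises(self):
        with pytest.raises(ValueError):
            exact_test([1], [1], -0.5)


class TestBH:
    def test_step_up_hand_computation(self):
        got = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert got == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_monotone_and_bounded(self, ps):
        fdr = bh_fdr(ps)
        assert (fdr >= np.asarray(ps) - 1e-12).all()
        assert (fdr <= 1 + 1e-12).all()
        order = np.argsort(ps)
        assert (np.diff(fdr[order]) >= -1e-12).all()


class TestCalls:
    def test_threshold_conjunction(self):
        df = pd.DataFrame(
            {
                "logFC": [2.71, -0.9, 1.5, -4.84],
                "fdr": [2.68e-77, 0.001, 0.2, 1e-10],
            },
            index=["MIR1512", "x", "y", "MIR2119"],
        )
        out = call_de(df)
        assert out.loc["MIR1512", "call"] == "up"
        assert out.loc["MIR2119", "call"] == "down"
        assert out.loc["x", "call"] == "ns"  # |logFC| < 1 despite small FDR
        assert out.loc["y", "call"] == "ns"  # FDR too large
        assert out.loc["y", "call_relaxed"] == "up"


@pytest.fixture(scope="module")
def fixed_matrix():
    counts = pd.DataFrame(
        {
            "c1": [500, 40, 1200, 10, 300, 80],
            "c2": [460, 55, 1100, 14, 280, 70],
            "s1": [520, 150, 300, 12, 310, 20],
            "s2": [480, 130, 350, 9, 290, 25],
        },
        index=[f"g{i}" for i in range(6)],
    )
    return CountMatrix(counts, COND)


class TestRunDe:
    def test_calls_and_ordering(self, fixed_matrix):
        res = run_de(fixed_matrix)
        assert list(res.index) == [f"g{i}" for i in range(6)]
        assert res.loc["g1", "call"] == "up"
        assert res.loc["g2", "call"] == "down"
        assert res.loc["g3", "call"] == "ns"
        assert (res["fdr"] >= res["PValue"] - 1e-12).all()

    def test_agrees_with_edger_exact_test(self, fixed_matrix, tmp_path):
        """Independent cross-check: the Bioconductor exact-test reference
        gives the same logFC (to 0.05), the same significance pattern and
        the same p-value ranking on a fixed matrix."""
        res = run_de(fixed_matrix)
        tsv = tmp_path / "cm.tsv"
        fixed_matrix.counts.to_csv(tsv, sep="\t")
        script = textwrap.dedent(
            f"""
            suppressMessages(library(edgeR))
            x <- read.delim("{tsv}", row.names=1)
            y <- DGEList(counts=x, group=factor(c("c","c","s","s")))
            y <- estimateCommonDisp(y)
            et <- exactTest(y)
            tt <- topTags(et, n=10, sort.by="none")$table
            write.csv(tt, "{tmp_path}/edger.csv")
            """
        )
        (tmp_path / "s.R").write_text(script)
        subprocess.run(
            ["Rscript", str(tmp_path / "s.R")], check=True, capture_output=True
        )
        ref = pd.read_csv(tmp_path / "edger.csv", index_col=0)
        assert np.allclose(res["logFC"], ref["logFC"], atol=0.05)
        assert (
            list(res["PValue"].rank()) == list(ref["PValue"].rank())
        )
        assert ((res["PValue"] < 1e-3) == (ref["PValue"] < 1e-3)).all()


class TestCalibration:
    def test_type_one_error_and_power(self):
        """Null type-I error near nominal and high recovery of 4-fold
        effects at moderate means, 2 vs 2 replicates, dispersion 0.1."""
        rng = np.random.default_rng(11)

        def nb(mu, phi, size):
            r = 1 / phi
            return rng.negative_binomial(r, r / (r + mu), size=size)

        n = 500
        mu = np.exp(rng.uniform(np.log(20), np.log(2000), size=n))
        null = pd.DataFrame(
            {c: nb(mu, 0.1, n) for c in COND}, index=[f"f{j}" for j in range(n)]
        )
        sizes = {c: 1e6 for c in COND}
        res = run_de(CountMatrix(null, COND, sizes))
        frac = (res["PValue"] < 0.05).mean()
        assert 0.02 <= frac <= 0.09

        mu2 = np.exp(rng.uniform(np.log(100), np.log(2000), size=n))
        alt = pd.DataFrame(
            {
                "c1": nb(mu2, 0.1, n),
                "c2": nb(mu2, 0.1, n),
                "s1": nb(4 * mu2, 0.1, n),
                "s2": nb(4 * mu2, 0.1, n),
            },
            index=[f"f{j}" for j in range(n)],
        )
        res2 = run_de(CountMatrix(alt, COND, sizes))
        assert (res2["call"] == "up").mean() >= 0.8
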