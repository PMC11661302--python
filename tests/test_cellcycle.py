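"""Signature phase scoring and the NB mitotic-cell caller against pmf-summation oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from intraseq import (
    NormalizedMatrix,
    ValidationError,
    annotate_phases,
    call_m_phase,
    fit_nb_null,
    signature_phase_score,
)


def brute_force_tail(null, count, support_max=5000):
    """P(X >= count) by direct pmf summation, independent of the survival function."""
    x = np.arange(count, support_max + 1)
    if null.family == "NB":
        pmf = stats.nbinom.pmf(x, null.r, null.p_success)
    else:
        pmf = stats.poisson.pmf(x, null.mu_hat)
    return pmf.sum()


class TestFitNBNull:
    def test_worked_moments_example(self):
        null = fit_nb_null([0, 0, 1, 1, 2, 8])
        assert null.mu_hat == pytest.approx(2.0)
        assert null.sigma2_hat == pytest.approx(46 / 6)
        assert null.family == "NB"
        assert null.r == pytest.approx(4 / (46 / 6 - 2), abs=1e-10)
        assert null.r == pytest.approx(0.70588, abs=1e-4)
        assert null.p_success == pytest.approx(2 / (46 / 6), abs=1e-10)
        assert null.p_success == pytest.approx(0.26087, abs=1e-4)

    def test_constant_counts_fall_back_to_poisson(self):
        null = fit_nb_null([3, 3, 3])
        assert null.family == "Poisson"
        assert null.mu_hat == pytest.approx(3.0)
        assert null.sigma2_hat == 0.0

    def test_variance_equal_mean_boundary_is_poisson(self):
        null = fit_nb_null([0, 1, 2, 3, 4])
        assert null.mu_hat == pytest.approx(2.0)
        assert null.sigma2_hat == pytest.approx(2.0)
        assert null.family == "Poisson"

    def test_too_few_counts_rejected(self):
        with pytest.raises(ValidationError):
            fit_nb_null([5])

    def test_all_zero_degenerate_poisson(self):
        null = fit_nb_null([0, 0, 0])
        assert null.degenerate
        calls = call_m_phase(pd.Series({"a": 0, "b": 3}), null)
        assert calls.set_index("cell").loc["b", "p_value"] > 0  # floored, flagged via family
        assert not calls.set_index("cell").loc["a", "is_M"]

    def test_moment_recovery_on_nb_draws(self):
        """Fit on 10,000 NB(mu=2, var=8) draws recovers mu within 3 SE."""
        rng = np.random.default_rng(17)
        r, p = 4 / 6, 2 / 8
        x = rng.negative_binomial(r, p, size=10_000)
        null = fit_nb_null(x)
        assert abs(null.mu_hat - 2.0) < 3 * np.sqrt(8 / 10_000)
        assert null.family == "NB"


class TestTailProbabilities:
    @pytest.mark.parametrize("counts", [[0, 0, 1, 1, 2, 8], [1, 1, 2, 2, 3, 3]])
    def test_tails_match_pmf_summation(self, counts):
        null = fit_nb_null(counts)
        xs = np.concatenate([np.arange(0, 50), [100, 500, 1000]])
        for x in xs:
            assert null.tail_prob(int(x)) == pytest.approx(
                brute_force_tail(null, int(x)), abs=1e-10
            )

    def test_poisson_worked_value(self):
        null = fit_nb_null([2, 2, 2, 2])  # Poisson(2)
        p = float(null.tail_prob(8))
        assert p == pytest.approx(1 - stats.poisson.cdf(7, 2), abs=1e-12)
        assert p == pytest.approx(1.097e-3, rel=5e-3)


class TestCallMPhase:
    def test_count_zero_has_p_one_and_never_m(self):
        null = fit_nb_null([0, 0, 1, 1, 2, 8])
        calls = call_m_phase(pd.Series({"a": 0, "b": 0}), null)
        assert np.allclose(calls["p_value"], 1.0)
        assert not calls["is_M"].any()

    def test_excluded_cells_not_tested(self):
        null = fit_nb_null([0, 1, 2, 3, 4, 8])
        calls = call_m_phase(pd.Series({"a": 0, "b": 50, "s1": 100}), null,
                             exclude={"s1"})
        assert set(calls["cell"]) == {"a", "b"}

    def test_is_m_iff_fdr_below_alpha(self):
        rng = np.random.default_rng(4)
        null = fit_nb_null(rng.negative_binomial(4 / 6, 0.25, size=500))
        counts = pd.Series(rng.negative_binomial(4 / 6, 0.25, size=200).astype(int),
                           index=[f"c{i}" for i in range(200)])
        counts.iloc[:5] = 80
        calls = call_m_phase(counts, null, alpha=0.05)
        assert calls["is_M"].equals(calls["fdr"] < 0.05)
        assert calls.set_index("cell").loc["c0", "is_M"]

    def test_negative_counts_rejected(self):
        null = fit_nb_null([0, 1, 2, 5])
        with pytest.raises(ValidationError):
            call_m_phase(pd.Series({"a": -1}), null)


def _expr_matrix(values, genes):
    values = np.asarray(values, float)
    return NormalizedMatrix(
        cells=[f"c{i}" for i in range(values.shape[0])],
        features=genes, values=values, method="rna_lognorm",
    )


class TestSignatureScoring:
    def test_all_zero_expression_gives_g1(self):
        genes = [f"g{i}" for i in range(30)]
        m = _expr_matrix(np.zeros((10, 30)), genes)
        out = signature_phase_score(m, ["g0", "g1"], ["g2", "g3"], n_bins=3, seed=0)
        assert (out["phase"] == "G1").all()
        assert np.allclose(out["s_score"], 0.0)
        assert np.allclose(out["g2m_score"], 0.0)

    def test_elevated_s_genes_label_s(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(40)]
        values = rng.normal(1.0, 0.1, size=(20, 40))
        s_genes, g2m_genes = ["g0", "g1", "g2"], ["g3", "g4", "g5"]
        values[:5, :3] *= 10  # first five cells: S signature 10x over background
        m = _expr_matrix(values, genes)
        out = signature_phase_score(m, s_genes, g2m_genes, n_bins=4, seed=0)
        assert (out.loc[:4, "phase"] == "S").all()
        # direct score check: mean(sig) - mean(ctrl) > 0 for those cells
        assert (out.loc[:4, "s_score"] > out.loc[:4, "g2m_score"]).all()

    def test_empty_gene_list_rejected(self):
        m = _expr_matrix(np.zeros((3, 5)), [f"g{i}" for i in range(5)])
        with pytest.raises(ValidationError):
            signature_phase_score(m, [], ["g1"], seed=0)

    def test_absent_signature_genes_listed_in_error(self):
        m = _expr_matrix(np.zeros((3, 5)), [f"g{i}" for i in range(5)])
        with pytest.raises(ValidationError, match="zz1"):
            signature_phase_score(m, ["zz1"], ["g1"], seed=0)

    def test_seed_reproducible(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(40)]
        m = _expr_matrix(rng.normal(size=(15, 40)), genes)
        a = signature_phase_score(m, ["g0", "g1"], ["g2", "g3"], seed=5)
        b = signature_phase_score(m, ["g0", "g1"], ["g2", "g3"], seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestAnnotatePhases:
    def test_m_call_overrides_signature_label(self):
        sig = pd.DataFrame(
            {"cell": [f"c{i}" for i in range(12)],
             "phase": ["S"] * 6 + ["G1"] * 3 + ["G2M"] * 3,
             "s_score": 0.0, "g2m_score": 0.0}
        )
        ph3 = pd.Series([0, 0, 1, 1, 2, 8, 0, 1, 90, 0, 85, 2],
                        index=[f"c{i}" for i in range(12)])
        annotated, null = annotate_phases(sig, ph3)
        ann = annotated.set_index("cell")
        assert null.family == "NB"
        assert ann.loc["c8", "phase"] == "M"
        assert ann.loc["c10", "phase"] == "M"
        assert ann.loc["c6", "phase"] == "G1"
        # S cells used for the fit keep their label and are not tested
        assert ann.loc["c0", "phase"] == "S"
        assert pd.isna(ann.loc["c0", "p_value"])
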