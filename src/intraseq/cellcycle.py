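"""Cell-cycle phase labels and the negative-binomial mitotic-cell caller.

RNA signature scoring assigns each cell an S or G2M score (mean expression
of the signature genes minus the mean of expression-matched control genes)
and a provisional phase: S or G2M when the corresponding score is the larger
and positive, otherwise G1. Because mitosis is transcriptionally close to
G2M, M-phase cells are not separable from RNA alone.

The mitotic caller instead uses the phospho-Histone-H3 (Ser10) antibody
channel. Non-mitotic cells are modelled as X ~ NB(mu, sigma^2), with the
null fitted by method of moments on the S-phase cells (temporally the
furthest from mitosis): mu_hat = (1/n) sum x_i and
sigma2_hat = (1/n) sum (x_i - mu_hat)^2. When sigma2_hat <= mu_hat the NB
moment inversion is undefined and the null degrades gracefully to
Poisson(mu_hat). Each remaining cell is tested upper-tail,
p = P(X >= x) = SF(x - 1), p-values are Benjamini-Hochberg adjusted, and
cells with adjusted p < alpha = 0.05 are called M phase, overriding their
signature label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import NormalizedMatrix, ValidationError
from .correlate import bh_adjust


@dataclass
class NBNull:
    """Method-of-moments null for phospho-H3 counts in non-mitotic cells.

    Moments use the biased (1/n) variance. For the NB family the derived
    shape is r = mu_hat^2 / (sigma2_hat - mu_hat) and success probability
    p_success = mu_hat / sigma2_hat; when sigma2_hat <= mu_hat the family is
    Poisson(mu_hat).
    """

    mu_hat: float
    sigma2_hat: float
    n: int
    family: str  # "NB" | "Poisson"
    r: float | None = None
    p_success: float | None = None

    def tail_prob(self, count: np.ndarray | int) -> np.ndarray:
        """P(X >= count): the upper-tail probability including the observed value."""
        count = np.asarray(count)
        if np.any(count < 0):
            raise ValidationError("counts must be non-negative")
        if self.family == "NB":
            p = stats.nbinom.sf(count - 1, self.r, self.p_success)
        else:
            p = stats.poisson.sf(count - 1, self.mu_hat)
        return np.asarray(p, dtype=float)

    @property
    def degenerate(self) -> bool:
        return self.family == "Poisson" and self.mu_hat == 0


def fit_nb_null(s_phase_counts) -> NBNull:
    """Fit the null from S-phase phospho-H3 UMI counts by method of moments."""
    x = np.asarray(s_phase_counts, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValidationError("need at least 2 S-phase counts to fit the null")
    if np.any(x < 0) or not np.allclose(x, np.round(x)):
        raise ValidationError("counts must be non-negative integers")
    n = x.size
    mu = float(x.mean())
    sigma2 = float(((x - mu) ** 2).mean())
    if sigma2 > mu:
        r = mu**2 / (sigma2 - mu)
        p = mu / sigma2
        return NBNull(mu_hat=mu, sigma2_hat=sigma2, n=n, family="NB", r=r, p_success=p)
    return NBNull(mu_hat=mu, sigma2_hat=sigma2, n=n, family="Poisson")


def call_m_phase(
    counts: pd.Series,
    null: NBNull,
    alpha: float = 0.05,
    exclude: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Upper-tail test of each cell's phospho-H3 count against the null.

    ``counts`` is indexed by cell; cells in ``exclude`` (typically the
    S-phase cells the null was fitted on) are not tested. p = P(X >= count),
    so a count of 0 always has p = 1; BH runs across all tested cells and
    is_M <=> adjusted p < alpha. A degenerate Poisson(0) null makes every
    positive count maximally significant; p-values are floored at the
    smallest positive double so they stay in (0, 1].
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    counts = pd.Series(counts)
    vals = counts.to_numpy()
    if np.any(vals < 0):
        raise ValidationError("counts must be non-negative")
    if exclude is not None:
        counts = counts[~counts.index.isin(set(exclude))]
    p = null.tail_prob(counts.to_numpy().astype(np.int64))
    p = np.maximum(p, np.nextafter(0.0, 1.0))
    fdr = bh_adjust(p)
    return pd.DataFrame(
        {
            "cell": counts.index,
            "count": counts.to_numpy(),
            "p_value": p,
            "fdr": fdr,
            "is_M": fdr < alpha,
            "alpha": alpha,
        }
    ).reset_index(drop=True)


def signature_phase_score(
    values: NormalizedMatrix,
    s_genes: Sequence[str],
    g2m_genes: Sequence[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Score each cell for S and G2M programs and assign a provisional phase.

    For each signature, the score is the mean normalized expression of the
    signature genes minus the mean of control genes sampled (without
    replacement, seeded) from the same mean-expression bins; genes are
    binned into ``n_bins`` equal-frequency bins. Phase: S when s_score is
    the strictly larger score and positive; G2M when g2m_score is at least
    as large and positive; otherwise G1.
    """
    if not s_genes or not g2m_genes:
        raise ValidationError("both signature gene lists must be non-empty")
    present = set(values.features)
    s_found = [g for g in s_genes if g in present]
    g2m_found = [g for g in g2m_genes if g in present]
    missing = [g for g in list(s_genes) + list(g2m_genes) if g not in present]
    if not s_found or not g2m_found:
        raise ValidationError(f"signature genes not found in matrix: {missing}")

    frame = values.to_frame()
    gene_means = frame.mean(axis=0)
    # equal-frequency bins on mean expression (rank-based, ties broken stably)
    ranks = gene_means.rank(method="first")
    bins = np.ceil(ranks / len(gene_means) * n_bins).astype(int)
    rng = np.random.default_rng(seed)

    def score(sig: list[str]) -> np.ndarray:
        ctrl: set[str] = set()
        sig_set = set(sig)
        for g in sig:
            pool = bins.index[(bins == bins[g]) & (~bins.index.isin(sig_set))]
            if len(pool) == 0:
                continue
            take = min(n_ctrl, len(pool))
            ctrl.update(rng.choice(pool, size=take, replace=False))
        sig_mean = frame[sig].mean(axis=1).to_numpy()
        ctrl_mean = frame[sorted(ctrl)].mean(axis=1).to_numpy() if ctrl else 0.0
        return sig_mean - ctrl_mean

    s_score = score(s_found)
    g2m_score = score(g2m_found)

    phase = np.full(len(values.cells), "G1", dtype=object)
    phase[(g2m_score >= s_score) & (g2m_score > 0)] = "G2M"
    phase[(s_score > g2m_score) & (s_score > 0)] = "S"
    out = pd.DataFrame(
        {"cell": values.cells, "phase": phase,
         "s_score": s_score, "g2m_score": g2m_score}
    )
    out.attrs["missing_signature_genes"] = missing
    return out


def annotate_phases(
    signature_labels: pd.DataFrame,
    ph3_counts: pd.Series,
    alpha: float = 0.05,
    exclude_s_phase: bool = True,
) -> tuple[pd.DataFrame, NBNull]:
    """Full re-annotation: fit the null on S-phase cells, call M, relabel.

    Cells called M override their signature phase; all other cells keep
    their signature label. By default the S-phase cells used to fit the
    null are not re-tested.
    """
    sig = signature_labels.set_index("cell")
    s_cells = sig.index[sig["phase"] == "S"]
    if len(s_cells) < 2:
        raise ValidationError("need at least 2 S-phase cells to fit the null")
    null = fit_nb_null(ph3_counts.reindex(s_cells).to_numpy())
    exclude = s_cells if exclude_s_phase else None
    calls = call_m_phase(ph3_counts, null, alpha=alpha, exclude=exclude)
    merged = sig.copy()
    merged["signature_phase"] = merged["phase"]
    m_cells = calls.loc[calls["is_M"], "cell"]
    merged.loc[merged.index.isin(set(m_cells)), "phase"] = "M"
    merged = merged.reset_index().merge(
        calls[["cell", "count", "p_value", "fdr", "is_M"]], on="cell", how="left"
    )
    merged["is_M"] = merged["is_M"].notna() & merged["is_M"].eq(True)
    return merged, null
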