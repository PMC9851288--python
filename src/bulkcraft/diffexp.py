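"""Two-group negative-binomial differential expression (classic exact test).

Counts for feature *g* in group *k* are modelled as NB(mean mu_gk,
dispersion phi) with variance mu + phi * mu^2.  The workflow mirrors the
classic count-based exact-test pipeline:

1. library sizes are pseudo-equalised by scaling each column to the
   geometric-mean library size (a documented approximation of
   quantile-to-quantile count adjustment);
2. a common dispersion is estimated by maximising the conditional
   log-likelihood, pooled over features, given each group's total;
3. tagwise dispersions shrink each feature's conditional likelihood towards
   the common curve through a weighted-likelihood penalty (prior weight =
   ``prior_weight`` equivalent features);
4. a two-sided exact conditional test is computed per feature given the
   feature's total count across both groups: under equal means the group-A
   total follows a negative hypergeometric distribution (binomial in the
   Poisson limit), and the two-sided p-value doubles the smaller tail.

The log2 fold-change uses a pseudo-count of 0.5 on the per-sample mean scale.
Multiple testing is controlled with Benjamini-Hochberg within a comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp

from .matrixio import ExpressionMatrix, MatrixIOError, MetadataTable

__all__ = [
    "DEResult",
    "DEComparison",
    "differential_expression",
    "compare_de",
    "volcano_table",
    "ma_table",
    "benjamini_hochberg",
    "exact_nb_test",
]

#: pseudo-count on the per-sample mean scale for fold-change computation
FC_PSEUDOCOUNT = 0.5


@dataclass
class DEResult:
    """Per-feature differential expression table.

    ``table`` columns: log2_fc, mean_expr, pvalue, padj, is_de.  The flag is
    padj < alpha AND |log2_fc| >= min_abs_log2_fc.
    """

    table: pd.DataFrame
    comparison_label: str
    alpha: float
    min_abs_log2_fc: float
    common_dispersion: float | None = None

    @property
    def de_features(self) -> list[str]:
        return list(self.table.index[self.table["is_de"]])


@dataclass
class DEComparison:
    table: pd.DataFrame  # log2_fc_1, log2_fc_2, is_de_1, is_de_2, concordance
    counts: dict[str, int]  # both / only_1 / only_2 / neither
    labels: tuple[str, str]


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# conditional likelihood machinery
# ---------------------------------------------------------------------------

def _cond_loglik(y: np.ndarray, groups: list[np.ndarray], r: float) -> np.ndarray:
    """Per-feature NB conditional log-likelihood given group totals.

    ``y`` is features x samples (pseudo-equalised), ``groups`` a list of
    column-index arrays.  With equal library sizes the likelihood conditional
    on each group's total does not depend on the group mean:

        sum_i lgamma(y_i + r) - n*lgamma(r) - lgamma(z + n*r) + lgamma(n*r)

    summed over the groups (terms free of r dropped).
    """
    tot = np.zeros(y.shape[0])
    for idx in groups:
        yy = y[:, idx]
        n = len(idx)
        z = yy.sum(axis=1)
        tot += gammaln(yy + r).sum(axis=1) - n * gammaln(r) - gammaln(z + n * r) + gammaln(n * r)
    return tot


def _estimate_common_dispersion(y: np.ndarray, groups: list[np.ndarray]) -> float:
    """Maximise the pooled conditional log-likelihood over the dispersion."""

    def neg(log_phi: float) -> float:
        r = np.exp(-log_phi)  # r = 1/phi
        return -float(_cond_loglik(y, groups, r).sum())

    res = minimize_scalar(neg, bounds=(np.log(1e-6), np.log(20.0)), method="bounded",
                          options={"xatol": 1e-4})
    return float(np.exp(res.x))


def _estimate_tagwise_dispersion(
    y: np.ndarray,
    groups: list[np.ndarray],
    common: float,
    prior_weight: float,
    n_grid: int = 25,
) -> np.ndarray:
    """Weighted-likelihood tagwise dispersions on a grid around the common one.

    Each feature maximises l_g(phi) + prior_weight * lbar(phi), where lbar is
    the mean conditional log-likelihood over all features; the grid spans
    common * 2^[-8, 8] and the argmax is refined by parabolic interpolation.
    """
    G = y.shape[0]
    grid = common * 2.0 ** np.linspace(-8, 8, n_grid)
    L = np.empty((G, n_grid))
    for k, phi in enumerate(grid):
        L[:, k] = _cond_loglik(y, groups, 1.0 / phi)
    pen = L + prior_weight * L.mean(axis=0)[None, :]
    best = np.argmax(pen, axis=1)

    # parabolic refinement in log2(phi) for interior maxima
    log_grid = np.log2(grid)
    out = grid[best].copy()
    inner = (best > 0) & (best < n_grid - 1)
    i = best[inner]
    rows = np.nonzero(inner)[0]
    y0, y1, y2 = pen[rows, i - 1], pen[rows, i], pen[rows, i + 1]
    denom = y0 - 2 * y1 + y2
    with np.errstate(divide="ignore", invalid="ignore"):
        shift = np.where(denom < 0, 0.5 * (y0 - y2) / denom, 0.0)
    shift = np.clip(shift, -1.0, 1.0)
    step = log_grid[1] - log_grid[0]
    out[rows] = 2.0 ** (log_grid[i] + shift * step)
    return out


# ---------------------------------------------------------------------------
# exact conditional test
# ---------------------------------------------------------------------------

def exact_nb_test(sum_a: float, sum_b: float, n_a: int, n_b: int, dispersion: float) -> float:
    """Two-sided exact conditional NB test for equal group means.

    Conditions on the total ``s = sum_a + sum_b`` (rounded to an integer).
    The group-A total then follows a negative hypergeometric law with shape
    (n_a / phi, n_b / phi); for dispersion below 1e-8 the Poisson-limit
    binomial with success probability n_a / (n_a + n_b) is used.  The
    two-sided p doubles the smaller of the two tails (capped at 1).
    """
    a_obs = max(int(round(sum_a)), 0)
    b_obs = max(int(round(sum_b)), 0)
    s = a_obs + b_obs  # rounding each group total keeps the test symmetric
    if s == 0:
        return 1.0
    k = np.arange(s + 1)
    if dispersion < 1e-8:
        p = n_a / (n_a + n_b)
        logp = (
            gammaln(s + 1) - gammaln(k + 1) - gammaln(s - k + 1)
            + k * np.log(p) + (s - k) * np.log1p(-p)
        )
    else:
        r = 1.0 / dispersion
        ra, rb = n_a * r, n_b * r
        logp = (
            gammaln(k + ra) - gammaln(k + 1)
            + gammaln(s - k + rb) - gammaln(s - k + 1)
        )
        logp -= logsumexp(logp)
    prob = np.exp(logp - logsumexp(logp))
    lower = float(prob[: a_obs + 1].sum())
    upper = float(prob[a_obs:].sum())
    return float(min(1.0, 2.0 * min(lower, upper)))


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def differential_expression(
    m: ExpressionMatrix,
    meta: MetadataTable,
    factor: str,
    level_A: str,
    level_B: str,
    alpha: float = 0.05,
    min_abs_log2_fc: float = 1.0,
    dispersion_mode: str = "tagwise",
    fixed_dispersion: float | None = None,
    prior_weight: float = 10.0,
) -> DEResult:
    """Negative-binomial exact-test DE between two metadata levels.

    The matrix is expected pre-normalised; no internal re-normalisation is
    performed beyond pseudo-equalisation of the column totals.  Fold changes
    are ``log2((mean_B + 0.5) / (mean_A + 0.5))`` on the pseudo-equalised
    scale, so a positive value means higher expression in ``level_B``.

    ``fixed_dispersion`` bypasses estimation (and, as the only such case,
    permits single-replicate groups, e.g. for the Poisson limit).
    """
    if dispersion_mode not in ("common", "tagwise"):
        raise MatrixIOError("dispersion_mode must be 'common' or 'tagwise'")
    meta = meta.harmonise(m)
    samples_a = meta.samples_for(factor, level_A)
    samples_b = meta.samples_for(factor, level_B)
    for lvl, ss in ((level_A, samples_a), (level_B, samples_b)):
        if not ss:
            raise MatrixIOError(f"level {lvl!r} not present in factor {factor!r}")
        if len(ss) < 2 and fixed_dispersion is None:
            raise MatrixIOError(f"replicates required: level {lvl!r} has {len(ss)} sample(s)")

    cols = samples_a + samples_b
    y = m.data[cols].to_numpy(dtype=float)
    lib = y.sum(axis=0)
    if (lib <= 0).any():
        bad = [cols[i] for i in np.nonzero(lib <= 0)[0]]
        raise MatrixIOError(f"all-zero column(s): {bad}")
    geo = float(np.exp(np.mean(np.log(lib))))
    y = y * (geo / lib)  # pseudo-equalised counts

    n_a, n_b = len(samples_a), len(samples_b)
    idx_a = np.arange(n_a)
    idx_b = np.arange(n_a, n_a + n_b)
    groups = [idx_a, idx_b]

    nonzero = y.sum(axis=1) > 0
    common: float | None = None
    if fixed_dispersion is not None:
        disp = np.full(y.shape[0], float(fixed_dispersion))
    else:
        common = _estimate_common_dispersion(y[nonzero], groups)
        if dispersion_mode == "common":
            disp = np.full(y.shape[0], common)
        else:
            disp = np.full(y.shape[0], common)
            disp[nonzero] = _estimate_tagwise_dispersion(y[nonzero], groups, common, prior_weight)

    mean_a = y[:, idx_a].mean(axis=1)
    mean_b = y[:, idx_b].mean(axis=1)
    log2_fc = np.log2((mean_b + FC_PSEUDOCOUNT) / (mean_a + FC_PSEUDOCOUNT))
    mean_expr = y.mean(axis=1)

    pvals = np.ones(y.shape[0])
    for g in np.nonzero(nonzero)[0]:
        pvals[g] = exact_nb_test(mean_a[g] * n_a, mean_b[g] * n_b, n_a, n_b, disp[g])
    log2_fc[~nonzero] = 0.0

    padj = benjamini_hochberg(pvals)
    is_de = (padj < alpha) & (np.abs(log2_fc) >= min_abs_log2_fc)
    table = pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "mean_expr": mean_expr,
            "pvalue": pvals,
            "padj": padj,
            "is_de": is_de,
        },
        index=pd.Index(m.feature_ids, name="feature"),
    )
    return DEResult(
        table=table,
        comparison_label=f"{level_A} vs {level_B}",
        alpha=alpha,
        min_abs_log2_fc=min_abs_log2_fc,
        common_dispersion=common,
    )


def compare_de(r1: DEResult, r2: DEResult) -> DEComparison:
    """Join two DE results on feature id and classify concordance."""
    shared = r1.table.index.intersection(r2.table.index)
    if shared.empty:
        raise MatrixIOError("DE results share no feature ids")
    t = pd.DataFrame(
        {
            "log2_fc_1": r1.table.loc[shared, "log2_fc"],
            "log2_fc_2": r2.table.loc[shared, "log2_fc"],
            "is_de_1": r1.table.loc[shared, "is_de"],
            "is_de_2": r2.table.loc[shared, "is_de"],
        }
    )
    cls = np.select(
        [
            t.is_de_1 & t.is_de_2,
            t.is_de_1 & ~t.is_de_2,
            ~t.is_de_1 & t.is_de_2,
        ],
        ["both", "only_1", "only_2"],
        default="neither",
    )
    t["concordance"] = cls
    counts = {c: int((cls == c).sum()) for c in ("both", "only_1", "only_2", "neither")}
    return DEComparison(table=t, counts=counts, labels=(r1.comparison_label, r2.comparison_label))


def volcano_table(r: DEResult) -> pd.DataFrame:
    """(log2_fc, -log10 padj, is_de); padj = 0 is clamped to the smallest
    positive double before taking the log."""
    padj = np.clip(r.table["padj"].to_numpy(), np.finfo(float).tiny, None)
    return pd.DataFrame(
        {
            "log2_fc": r.table["log2_fc"],
            "neg_log10_padj": np.where(r.table["padj"].to_numpy() >= 1.0, 0.0, -np.log10(padj)),
            "is_de": r.table["is_de"],
        },
        index=r.table.index,
    )


def ma_table(r: DEResult) -> pd.DataFrame:
    """(mean expression on log2 scale with the fold-change pseudo-count, log2_fc, is_de)."""
    return pd.DataFrame(
        {
            "log2_mean_expr": np.log2(r.table["mean_expr"].to_numpy() + FC_PSEUDOCOUNT),
            "log2_fc": r.table["log2_fc"],
            "is_de": r.table["is_de"],
        },
        index=r.table.index,
    )
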