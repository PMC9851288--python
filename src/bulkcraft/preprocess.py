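"""Noise thresholding and normalisation of count matrices.

Low-abundance counts in bulk sequencing are dominated by technical noise: the
between-sample correlation of counts collapses as abundance decreases.  The
counts-based noise detector exploits this by sliding a window over features
sorted by mean abundance and recording, per window, the mean pairwise Pearson
correlation between samples.  The noise threshold is the abundance at which
the correlation first rises above a similarity threshold and stays there.

Five normalisation methods are provided: quantile, RPM (reads per million),
median scaling, median-of-ratios size factors, and TMM (trimmed mean of
M-values).  Normalisation always follows denoising; denoised-but-unnormalised
matrices are the intended input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .matrixio import ExpressionMatrix, MatrixIOError

__all__ = [
    "NoiseResult",
    "NormalisationSpec",
    "detect_noise_threshold",
    "apply_noise_removal",
    "normalise",
    "median_of_ratios_factors",
    "tmm_factors",
    "NORM_METHODS",
]

NORM_METHODS = ("quantile", "rpm", "median_of_ratios", "tmm", "median")


@dataclass
class NoiseResult:
    """Outcome of the sliding-window noise scan.

    ``threshold`` is in the abundance units of the input matrix (mean count
    across samples); ``math.inf`` flags the degenerate case where no window
    reached the similarity threshold.  ``window_stats`` holds
    (window mean abundance, mean pairwise correlation) in increasing-abundance
    order.  ``removed_feature_ids`` lists features whose mean abundance falls
    below the threshold.
    """

    threshold: float
    window_stats: list[tuple[float, float]] = field(default_factory=list)
    removed_feature_ids: list[str] = field(default_factory=list)

    @property
    def degenerate(self) -> bool:
        return not np.isfinite(self.threshold)


@dataclass
class NormalisationSpec:
    method: str
    # TMM parameters; ignored by the other methods
    trim_m: float = 0.30
    trim_a: float = 0.05

    def __post_init__(self) -> None:
        if self.method not in NORM_METHODS:
            raise MatrixIOError(f"unknown normalisation {self.method!r}; expected one of {NORM_METHODS}")
        if not (0 <= self.trim_m < 0.5 and 0 <= self.trim_a < 0.5):
            raise MatrixIOError("trim fractions must lie in [0, 0.5)")


# ---------------------------------------------------------------------------
# noise detection
# ---------------------------------------------------------------------------

def _pairwise_mean_correlation(block: np.ndarray) -> float:
    """Mean Pearson correlation over all sample pairs within a window.

    A zero-variance column contributes correlation 0 to each of its pairs.
    """
    n_samples = block.shape[1]
    sd = block.std(axis=0)
    ok = sd > 0
    total = 0.0
    n_pairs = 0
    if ok.sum() >= 2:
        sub = block[:, ok]
        c = np.corrcoef(sub, rowvar=False)
        iu = np.triu_indices_from(c, k=1)
        total += float(np.sum(c[iu]))
    n_pairs = n_samples * (n_samples - 1) // 2
    return total / n_pairs


def detect_noise_threshold(
    m: ExpressionMatrix,
    window_size: int = 100,
    step: int = 10,
    similarity_threshold: float = 0.25,
) -> NoiseResult:
    """Scan abundance-sorted windows for the noise/signal boundary.

    Features are sorted by mean abundance across samples; windows of
    ``window_size`` features advance with stride ``step``.  The threshold is
    the mean abundance of the first window whose mean pairwise correlation
    reaches ``similarity_threshold`` *and* stays above it in every later
    window; +inf if no such window exists.
    """
    if not (0 < similarity_threshold < 1):
        raise MatrixIOError("similarity_threshold must lie in (0, 1)")
    if window_size < 1 or step < 1:
        raise MatrixIOError("window_size and step must be positive")
    if m.n_samples < 2:
        raise MatrixIOError("noise detection needs at least 2 samples")
    if window_size > m.n_features:
        raise MatrixIOError(
            f"window_size {window_size} exceeds number of features {m.n_features}"
        )

    means = m.data.mean(axis=1)
    # deterministic order: abundance, then feature id
    order = means.to_frame("mu").assign(fid=means.index).sort_values(["mu", "fid"]).index
    vals = m.data.loc[order].to_numpy(dtype=float)
    mu = means.loc[order].to_numpy(dtype=float)

    starts = list(range(0, m.n_features - window_size + 1, step))
    stats = []
    for s in starts:
        block = vals[s : s + window_size]
        stats.append((float(mu[s : s + window_size].mean()), _pairwise_mean_correlation(block)))

    corr = np.array([c for _, c in stats])
    above = corr >= similarity_threshold
    # first index from which all remaining windows stay above the threshold
    threshold = np.inf
    suffix_ok = np.logical_and.accumulate(above[::-1])[::-1]
    hits = np.nonzero(suffix_ok)[0]
    if hits.size:
        threshold = stats[hits[0]][0]

    removed = [fid for fid in m.feature_ids if means.loc[fid] < threshold] if np.isfinite(threshold) else []
    return NoiseResult(threshold=float(threshold), window_stats=stats, removed_feature_ids=removed)


def apply_noise_removal(
    m: ExpressionMatrix,
    nr: NoiseResult,
    mode: str = "drop",
) -> ExpressionMatrix:
    """Remove (or floor) sub-threshold features; output state = ``denoised``.

    ``drop`` removes features with mean abundance below the threshold;
    ``floor`` raises every value below the threshold to the threshold, then
    drops features left constant.
    """
    if mode not in ("drop", "floor"):
        raise MatrixIOError(f"unknown mode {mode!r}; expected drop or floor")
    if nr.degenerate:
        raise MatrixIOError(
            "noise threshold is undefined (no window reached the similarity "
            "threshold); inspect window_stats and supply a manual threshold"
        )
    if mode == "drop":
        keep = m.data.mean(axis=1) >= nr.threshold
        out = m.data.loc[keep].copy()
    else:
        out = m.data.clip(lower=nr.threshold)
        keep = out.nunique(axis=1) > 1
        # flooring may leave a feature constant across samples: uninformative
        out = out.loc[keep]
    return m.with_data(out, state="denoised")


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def _quantile_normalise(vals: np.ndarray) -> np.ndarray:
    """Classic quantile normalisation; ties receive the mean reference value
    of their tied ranks."""
    from scipy.stats import rankdata

    ref = np.sort(vals, axis=0).mean(axis=1)
    n = vals.shape[0]
    out = np.empty_like(vals, dtype=float)
    grid = np.arange(n, dtype=float)
    for j in range(vals.shape[1]):
        r = rankdata(vals[:, j], method="average") - 1.0
        out[:, j] = np.interp(r, grid, ref)
    return out


def median_of_ratios_factors(m: ExpressionMatrix) -> pd.Series:
    """Size factors: per sample, the median ratio to the geometric-mean
    pseudo-reference over features positive in every sample."""
    vals = m.values
    all_pos = (vals > 0).all(axis=1)
    if not all_pos.any():
        raise MatrixIOError("median-of-ratios: no feature is positive in every sample")
    logs = np.log(vals[all_pos])
    ref = logs.mean(axis=1)  # log geometric mean per feature
    factors = np.exp(np.median(logs - ref[:, None], axis=0))
    return pd.Series(factors, index=m.sample_ids, name="size_factor")


def tmm_factors(
    m: ExpressionMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ref_sample: str | None = None,
) -> pd.Series:
    """TMM scaling factors, rescaled to multiply to 1.

    Per non-reference sample: M- and A-values against the reference over
    features positive in both, double trim (``trim_m`` by M, ``trim_a`` by A),
    then a precision-weighted mean of the surviving M-values with inverse
    asymptotic binomial variance weights.  The reference is the sample whose
    75th percentile of positive values is closest to the mean such percentile.
    """
    from scipy.stats import rankdata

    vals = m.values
    lib = vals.sum(axis=0)
    if (lib <= 0).any():
        bad = [m.sample_ids[i] for i in np.nonzero(lib <= 0)[0]]
        raise MatrixIOError(f"all-zero column(s): {bad}")

    q75 = np.array([np.quantile(col[col > 0], 0.75) if (col > 0).any() else 0.0 for col in vals.T])
    if ref_sample is None:
        ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    else:
        ref_idx = m.sample_ids.index(ref_sample)

    xr, nr = vals[:, ref_idx], lib[ref_idx]
    log_factors = np.zeros(m.n_samples)
    for j in range(m.n_samples):
        if j == ref_idx:
            continue
        xs, ns = vals[:, j], lib[j]
        ok = (xs > 0) & (xr > 0)
        if not ok.any():
            continue
        ps, pr = xs[ok] / ns, xr[ok] / nr
        mvals = np.log2(ps / pr)
        avals = 0.5 * np.log2(ps * pr)
        w = (ns - xs[ok]) / (ns * xs[ok]) + (nr - xr[ok]) / (nr * xr[ok])

        n = ok.sum()
        rm = rankdata(mvals)
        ra = rankdata(avals)
        lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if not keep.any() or w[keep].sum() == 0:
            log_factors[j] = 0.0
            continue
        wm = float(np.sum(w[keep] * mvals[keep]) / np.sum(w[keep]))
        log_factors[j] = wm if abs(wm) > 1e-10 else 0.0

    # rescale so the factors multiply to 1
    log_factors -= log_factors.mean()
    return pd.Series(2.0 ** log_factors, index=m.sample_ids, name="tmm_factor")


def normalise(
    m: ExpressionMatrix,
    spec: NormalisationSpec | str,
    return_factors: bool = False,
) -> ExpressionMatrix | tuple[ExpressionMatrix, pd.Series | None]:
    """Apply one of the five normalisation methods; output state = ``normalised``.

    quantile
        every column is mapped onto the across-column mean order statistics.
    rpm
        each value scaled by 1e6 / column total (library size 1e6).
    median
        each value divided by its column median.
    median_of_ratios
        each value divided by the sample's median-of-ratios size factor.
    tmm
        each value divided by (library size x TMM factor), with factors
        rescaled to multiply to 1.

    With ``return_factors=True`` also returns the per-sample scaling factors
    (None for quantile, which is not a per-sample scaling).
    """
    if isinstance(spec, str):
        spec = NormalisationSpec(spec)
    if m.state == "raw":
        warnings.warn("normalising a raw matrix; consider denoising first", stacklevel=2)
    vals = m.values
    lib = vals.sum(axis=0)
    factors: pd.Series | None = None

    if spec.method == "rpm":
        if (lib <= 0).any():
            bad = [m.sample_ids[i] for i in np.nonzero(lib <= 0)[0]]
            raise MatrixIOError(f"all-zero column(s): {bad}")
        factors = pd.Series(lib / 1e6, index=m.sample_ids, name="rpm_factor")
        out = vals * (1e6 / lib)
    elif spec.method == "median":
        med = np.median(vals, axis=0)
        if (med <= 0).any():
            bad = [m.sample_ids[i] for i in np.nonzero(med <= 0)[0]]
            raise MatrixIOError(
                f"column median is 0 for {bad}; denoise the matrix before median normalisation"
            )
        factors = pd.Series(med, index=m.sample_ids, name="median_factor")
        out = vals / med
    elif spec.method == "quantile":
        out = _quantile_normalise(vals)
    elif spec.method == "median_of_ratios":
        factors = median_of_ratios_factors(m)
        out = vals / factors.to_numpy()
    else:  # tmm
        factors = tmm_factors(m, trim_m=spec.trim_m, trim_a=spec.trim_a)
        out = vals / (lib * factors.to_numpy())

    res = m.with_data(pd.DataFrame(out, index=m.feature_ids, columns=m.sample_ids), state="normalised")
    if return_factors:
        return res, factors
    return res
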