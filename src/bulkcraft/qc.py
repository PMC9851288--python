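"""Sample-similarity diagnostics: Jaccard similarity, PCA, Z-score matrices."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .matrixio import ExpressionMatrix, MatrixIOError

__all__ = ["QCResult", "jaccard_matrix", "pca", "zscore_matrix", "compute_qc"]

log = logging.getLogger(__name__)


@dataclass
class QCResult:
    jsi: pd.DataFrame                 # sample x sample, symmetric, diag 1
    pca_coords: pd.DataFrame          # sample x component
    pca_variance_fraction: np.ndarray


def _top_set(col: pd.Series, k: int) -> frozenset[str]:
    # highest value first; ties broken by feature id ascending
    order = sorted(col.index, key=lambda fid: (-col[fid], fid))
    return frozenset(order[:k])


def jaccard_matrix(
    m: ExpressionMatrix,
    top_fraction: float = 0.25,
    min_value: float | None = None,
) -> pd.DataFrame:
    """Jaccard similarity index between per-sample top-expressed feature sets.

    Each sample's set holds the ceil(top_fraction * n_features) features with
    the highest value in that sample (ties by feature id).  Alternatively
    ``min_value`` selects all features at or above an absolute cut, in which
    case ``top_fraction`` is ignored.
    """
    if min_value is None and not (0 < top_fraction <= 1):
        raise MatrixIOError("top_fraction must lie in (0, 1]")
    sets = {}
    for s in m.sample_ids:
        col = m.data[s]
        if min_value is not None:
            sets[s] = frozenset(col.index[col >= min_value])
        else:
            sets[s] = _top_set(col, math.ceil(top_fraction * m.n_features))
    ids = m.sample_ids
    out = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            u = len(sets[a] | sets[b])
            j = len(sets[a] & sets[b]) / u if u else 1.0
            out.loc[a, b] = out.loc[b, a] = j
    return out


def pca(
    m: ExpressionMatrix,
    n_components: int | None = None,
    scale_features: bool = False,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Project samples onto principal axes of the feature space.

    Features are centred (and optionally unit-scaled; zero-variance features
    are then dropped and logged).  The decomposition is a plain SVD with a
    deterministic sign convention: each component's loading vector is oriented
    so that its largest-magnitude entry is positive.

    Returns (coords: sample x component DataFrame, variance fractions).
    Variance fractions are relative to the total variance, so they sum to <= 1
    when fewer than all components are requested.
    """
    X = m.values.T  # samples x features
    n_max = min(m.n_samples, m.n_features)
    if n_components is None:
        n_components = n_max
    if not (1 <= n_components <= n_max):
        raise MatrixIOError(f"n_components must lie in [1, {n_max}]")
    Xc = X - X.mean(axis=0)
    if scale_features:
        sd = X.std(axis=0)
        keep = sd > 0
        if not keep.all():
            log.info("pca: dropping %d zero-variance feature(s) under scaling", int((~keep).sum()))
        Xc = Xc[:, keep] / sd[keep]
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    for k in range(Vt.shape[0]):
        i = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, i] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    coords = U[:, :n_components] * S[:n_components]
    total_var = float((Xc ** 2).sum())
    var_frac = (S[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    cols = [f"PC{k + 1}" for k in range(n_components)]
    return pd.DataFrame(coords, index=m.sample_ids, columns=cols), var_frac


def zscore_matrix(m: ExpressionMatrix, feature_subset: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-feature Z-scores across samples (population standard deviation).

    Constant features map to all-zero rows.
    """
    if feature_subset is None:
        sub = m.data
    else:
        feature_subset = list(feature_subset)
        if not feature_subset:
            raise MatrixIOError("feature subset is empty")
        unknown = [f for f in feature_subset if f not in m.data.index]
        if unknown:
            raise MatrixIOError(f"unknown feature id(s): {unknown}")
        sub = m.data.loc[feature_subset]
    vals = sub.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (vals - mu) / sd, 0.0)
    return pd.DataFrame(z, index=sub.index, columns=sub.columns)


def compute_qc(
    m: ExpressionMatrix,
    top_fraction: float = 0.25,
    n_components: int = 2,
    scale_features: bool = False,
) -> QCResult:
    """Bundle JSI and PCA into one QC summary."""
    coords, vf = pca(m, n_components=min(n_components, min(m.n_samples, m.n_features)), scale_features=scale_features)
    return QCResult(jsi=jaccard_matrix(m, top_fraction=top_fraction), pca_coords=coords, pca_variance_fraction=vf)
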