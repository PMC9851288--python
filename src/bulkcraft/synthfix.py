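"""Seeded synthetic-data generators with recorded ground truth.

Every input the pipeline consumes can be generated here: negative-binomial
count matrices with planted differential expression and a planted technical-
noise regime, expression matrices with planted linear regulatory edges,
per-sample peak calls with coverage tracks, and genomic coordinates.  Each
generator is a pure function of its parameters and seed, and returns the
ground truth needed to score downstream recovery.

Counts use the mean-dispersion NB parameterisation with variance
``mu + phi * mu**2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrixio import ExpressionMatrix, GenomicInterval, MatrixIOError, MetadataTable
from .peaks import Coverage, Peak

__all__ = [
    "SyntheticTruth",
    "simulate_counts",
    "simulate_grn_expression",
    "simulate_peaks",
    "simulate_coords",
]


@dataclass
class SyntheticTruth:
    """Ground truth planted by a generator."""

    de_features: dict[str, float] = field(default_factory=dict)   # feature -> signed log2 FC
    regulators: list[str] = field(default_factory=list)
    targets: list[str] = field(default_factory=list)
    edges: list[tuple[str, str, float]] = field(default_factory=list)  # (reg, tgt, effect)
    noise_boundary: float | None = None      # abundance below which counts are exchangeable
    noise_features: list[str] = field(default_factory=list)
    peak_components: dict[str, list[str]] = field(default_factory=dict)  # region id -> peak ids

    def to_dict(self) -> dict:
        return {
            "de_features": self.de_features,
            "regulators": self.regulators,
            "targets": self.targets,
            "edges": [list(e) for e in self.edges],
            "noise_boundary": self.noise_boundary,
            "noise_features": self.noise_features,
            "peak_components": self.peak_components,
        }


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws with variance mu + phi mu^2 (Poisson for phi = 0)."""
    if dispersion <= 0:
        return rng.poisson(mean).astype(float)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p).astype(float)


def simulate_counts(
    n_features: int = 2000,
    n_samples_per_group: int = 3,
    groups: tuple[str, ...] = ("A", "B"),
    baseline_log2_mean_range: tuple[float, float] = (3.0, 10.0),
    dispersion: float = 0.1,
    de_fraction: float = 0.1,
    de_log2fc: float = 2.0,
    noise_fraction: float = 0.0,
    noise_max_count: int = 5,
    seed: int = 0,
) -> tuple[ExpressionMatrix, MetadataTable, SyntheticTruth]:
    """NB count matrix with planted DE and an optional exchangeable-noise tier.

    Baseline means are log2-uniform over ``baseline_log2_mean_range`` (8 to
    1024 counts by default, the informative range of a desk-scale bulk
    library).  A ``de_fraction`` of features shifts every non-first group's
    mean by ``de_log2fc`` with random sign.  A ``noise_fraction`` of features
    is replaced with uniform counts in [0, noise_max_count], independent
    across samples, emulating the abundance tier where technical noise
    dominates; their planted boundary is recorded in the truth.
    """
    if not (0 <= de_fraction <= 1 and 0 <= noise_fraction <= 1):
        raise MatrixIOError("fractions must lie in [0, 1]")
    if de_fraction + noise_fraction > 1:
        raise MatrixIOError("de_fraction + noise_fraction must be <= 1")
    if n_features < 1 or n_samples_per_group < 1 or len(groups) < 2:
        raise MatrixIOError("need >= 1 feature, >= 1 sample/group and >= 2 groups")
    if dispersion < 0:
        raise MatrixIOError("dispersion must be >= 0")
    lo, hi = baseline_log2_mean_range
    if not lo < hi:
        raise MatrixIOError("baseline_log2_mean_range must be increasing")

    rng = np.random.default_rng(seed)
    width = len(str(n_features))
    fids = [f"g{i + 1:0{width}d}" for i in range(n_features)]
    samples = [f"{g}_{j + 1}" for g in groups for j in range(n_samples_per_group)]

    base = 2.0 ** rng.uniform(lo, hi, size=n_features)
    n_noise = int(round(noise_fraction * n_features))
    n_de = int(round(de_fraction * n_features))
    perm = rng.permutation(n_features)
    noise_idx = perm[:n_noise]
    de_idx = perm[n_noise : n_noise + n_de]
    signs = rng.choice([-1.0, 1.0], size=n_de)

    counts = np.empty((n_features, len(samples)))
    col = 0
    for gi, _g in enumerate(groups):
        mu = base.copy()
        if gi > 0:  # planted effect applies to every non-reference group
            mu[de_idx] = base[de_idx] * 2.0 ** (signs * de_log2fc)
        for _ in range(n_samples_per_group):
            counts[:, col] = _nb_sample(rng, mu, dispersion)
            col += 1
    counts[noise_idx] = rng.integers(0, noise_max_count + 1,
                                     size=(n_noise, len(samples))).astype(float)

    data = pd.DataFrame(counts, index=fids, columns=samples)
    meta = MetadataTable(pd.DataFrame(
        {"condition": [g for g in groups for _ in range(n_samples_per_group)]},
        index=samples,
    ))
    truth = SyntheticTruth(
        de_features={fids[i]: float(s * de_log2fc) for i, s in zip(de_idx, signs)},
        noise_boundary=float(noise_max_count) if n_noise else None,
        noise_features=sorted(fids[i] for i in noise_idx),
    )
    return ExpressionMatrix(data, state="raw"), meta, truth


def simulate_grn_expression(
    n_genes: int = 20,
    n_edges: int = 10,
    n_samples: int = 50,
    effect_snr: float = 5.0,
    n_regulators: int | None = None,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Expression with planted linear regulator -> target effects.

    The first ``n_regulators`` genes (half by default) are independent
    standard-normal drivers; edges are sampled without replacement from the
    regulator x target grid, and each target is the sum of its regulators'
    contributions plus Gaussian noise whose standard deviation is the signal
    standard deviation divided by ``effect_snr``.  Targets with no incoming
    edge are independent noise.  Values are affinely shifted to a positive
    abundance scale (100 + 10 z, floored at 0), which preserves all linear
    relations.
    """
    if n_regulators is None:
        n_regulators = n_genes // 2
    if not (1 <= n_regulators < n_genes):
        raise MatrixIOError("n_regulators must lie in [1, n_genes)")
    n_targets = n_genes - n_regulators
    if n_edges > n_regulators * n_targets:
        raise MatrixIOError(
            f"n_edges {n_edges} exceeds regulator x target capacity {n_regulators * n_targets}"
        )
    if n_samples < 3 or effect_snr <= 0:
        raise MatrixIOError("need n_samples >= 3 and effect_snr > 0")

    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    regs = [f"r{i + 1:0{width}d}" for i in range(n_regulators)]
    tgts = [f"t{i + 1:0{width}d}" for i in range(n_targets)]
    pairs = [(r, t) for r in regs for t in tgts]
    chosen = [pairs[i] for i in rng.choice(len(pairs), size=n_edges, replace=False)]

    z = {r: rng.standard_normal(n_samples) for r in regs}
    edges = []
    incoming: dict[str, list[tuple[str, float]]] = {}
    for r, t in chosen:
        effect = float(rng.choice([-1.0, 1.0]))
        edges.append((r, t, effect))
        incoming.setdefault(t, []).append((r, effect))
    for t in tgts:
        if t in incoming:
            signal = np.sum([eff * z[r] for r, eff in incoming[t]], axis=0)
            noise_sd = signal.std() / effect_snr
            z[t] = signal + rng.standard_normal(n_samples) * noise_sd
        else:
            z[t] = rng.standard_normal(n_samples)

    data = pd.DataFrame(
        {f"s{j + 1}": [max(0.0, 100.0 + 10.0 * z[g][j]) for g in regs + tgts]
         for j in range(n_samples)},
        index=regs + tgts,
    )
    truth = SyntheticTruth(regulators=regs, targets=tgts,
                           edges=sorted(edges))
    return ExpressionMatrix(data, state="normalised"), truth


def simulate_peaks(
    n_samples: int = 3,
    n_true_regions: int = 50,
    region_width: int = 400,
    gap: int = 2000,
    jitter_bp: int = 20,
    coverage_height_range: tuple[float, float] = (5.0, 50.0),
    seed: int = 0,
) -> tuple[dict[str, list[Peak]], dict[str, Coverage], SyntheticTruth]:
    """Per-sample peak calls and coverage tracks over shared true regions.

    True regions of ``region_width`` bp are laid out with ``gap`` bp between
    them (so peaks from different regions can never match); each sample's
    call jitters both ends by up to ``jitter_bp`` and carries uniform
    coverage at a per-(sample, region) height.  The planted co-membership of
    peaks per region is recorded in the truth.
    """
    if jitter_bp * 2 >= region_width:
        raise MatrixIOError("jitter must be smaller than half the region width")
    if gap <= 4 * jitter_bp:
        raise MatrixIOError("gap too small: jittered peaks could bridge regions")
    rng = np.random.default_rng(seed)
    samples = [f"chip_{i + 1}" for i in range(n_samples)]
    peak_sets: dict[str, list[Peak]] = {s: [] for s in samples}
    seg_lists: dict[str, dict[str, list[tuple[int, int, float]]]] = {s: {"chr1": []} for s in samples}
    truth = SyntheticTruth()

    pos = 1000
    for k in range(n_true_regions):
        start, end = pos, pos + region_width
        region_id = f"chr1:{start}-{end}"
        members = []
        for s in samples:
            js = int(rng.integers(-jitter_bp, jitter_bp + 1))
            je = int(rng.integers(-jitter_bp, jitter_bp + 1))
            iv = GenomicInterval("chr1", start + js, end + je)
            p = Peak(iv, sample_id=s)
            peak_sets[s].append(p)
            members.append(p.peak_id)
            height = float(rng.uniform(*coverage_height_range))
            seg_lists[s]["chr1"].append((iv.start, iv.end, height))
        truth.peak_components[region_id] = sorted(members)
        pos = end + gap

    coverages = {s: Coverage(seg_lists[s]) for s in samples}
    return peak_sets, coverages, truth


def simulate_coords(
    features: list[str],
    seed: int = 0,
    chroms: tuple[str, ...] = ("chr1", "chr2", "chr3"),
    width_range: tuple[int, int] = (500, 5000),
    gap_range: tuple[int, int] = (1000, 20000),
) -> dict[str, GenomicInterval]:
    """Non-overlapping stranded intervals for the given features."""
    rng = np.random.default_rng(seed)
    out: dict[str, GenomicInterval] = {}
    cursors = {c: 1000 for c in chroms}
    for fid in features:
        chrom = chroms[int(rng.integers(len(chroms)))]
        width = int(rng.integers(*width_range))
        start = cursors[chrom] + int(rng.integers(*gap_range))
        strand = "+" if rng.random() < 0.5 else "-"
        out[fid] = GenomicInterval(chrom, start, start + width, strand)
        cursors[chrom] = start + width
    return out
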