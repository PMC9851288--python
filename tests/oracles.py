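"""Independent brute-force oracles used to cross-check the implementation.

Each function here is a deliberately naive, literal transcription of the
defining formula or an exhaustive enumeration; none shares code with the
package modules it checks.
"""

from __future__ import annotations

import math

import numpy as np


def naive_tmm_factors(counts: np.ndarray, trim_m: float = 0.30, trim_a: float = 0.05) -> np.ndarray:
    """Step-by-step trim-and-weight TMM factors, rescaled to product 1.

    Literal transcription: pick the reference column whose 75th percentile of
    positive values is closest to the mean such percentile; per column keep
    genes positive in both, compute M, A and inverse binomial-variance
    weights, drop the top/bottom trim_m by M-rank and trim_a by A-rank
    (average ranks), and exponentiate the weighted mean M.
    """
    lib = counts.sum(axis=0)
    q75 = []
    for j in range(counts.shape[1]):
        col = counts[:, j]
        q75.append(np.quantile(col[col > 0], 0.75))
    q75 = np.array(q75)
    ref = int(np.argmin(np.abs(q75 - q75.mean())))

    logf = np.zeros(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        keep_genes = [g for g in range(counts.shape[0])
                      if counts[g, j] > 0 and counts[g, ref] > 0]
        M, A, W = [], [], []
        for g in keep_genes:
            ps = counts[g, j] / lib[j]
            pr = counts[g, ref] / lib[ref]
            M.append(math.log2(ps / pr))
            A.append(0.5 * math.log2(ps * pr))
            W.append((lib[j] - counts[g, j]) / (lib[j] * counts[g, j])
                     + (lib[ref] - counts[g, ref]) / (lib[ref] * counts[g, ref]))
        n = len(M)

        def avg_ranks(xs):
            order = sorted(range(n), key=lambda i: xs[i])
            ranks = [0.0] * n
            i = 0
            while i < n:
                k = i
                while k + 1 < n and xs[order[k + 1]] == xs[order[i]]:
                    k += 1
                r = (i + k) / 2 + 1
                for idx in order[i:k + 1]:
                    ranks[idx] = r
                i = k + 1
            return ranks

        rm, ra = avg_ranks(M), avg_ranks(A)
        lo_m, hi_m = math.floor(n * trim_m) + 1, n - math.floor(n * trim_m)
        lo_a, hi_a = math.floor(n * trim_a) + 1, n - math.floor(n * trim_a)
        num = den = 0.0
        for i in range(n):
            if lo_m <= rm[i] <= hi_m and lo_a <= ra[i] <= hi_a:
                num += W[i] * M[i]
                den += W[i]
        wm = num / den if den > 0 else 0.0
        logf[j] = wm if abs(wm) > 1e-10 else 0.0

    logf = logf - logf.mean()
    return 2.0 ** logf


def hypergeom_tail_sum(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] for X ~ Hypergeom(N, K, n) by direct summation of
    C(K, i) C(N-K, n-i) / C(N, n)."""
    total = 0.0
    denom = math.comb(N, n)
    for i in range(k, min(K, n) + 1):
        if n - i > N - K:
            continue
        total += math.comb(K, i) * math.comb(N - K, n - i) / denom
    return min(total, 1.0)


def pca_by_covariance(X: np.ndarray, n_components: int) -> tuple[np.ndarray, np.ndarray]:
    """Sample coordinates via eigendecomposition of the sample covariance
    (Gram) matrix of the centred data; eigenvectors sign-aligned so the
    largest-magnitude feature loading is positive.

    Returns (coords, eigenvalue-based variance fractions).
    """
    Xc = X - X.mean(axis=0)
    G = Xc @ Xc.T
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0, None)
    coords = np.zeros((X.shape[0], n_components))
    for kcomp in range(n_components):
        lam = evals[kcomp]
        if lam <= 1e-12:
            continue
        u = evecs[:, kcomp]
        loading = Xc.T @ u / math.sqrt(lam)
        i = int(np.argmax(np.abs(loading)))
        sign = 1.0 if loading[i] >= 0 else -1.0
        coords[:, kcomp] = sign * u * math.sqrt(lam)
    var_frac = evals[:n_components] / evals.sum() if evals.sum() > 0 else np.zeros(n_components)
    return coords, var_frac


def binomial_conditional_two_sided_p(a: int, b: int) -> float:
    """Two-sided exact conditional p in the Poisson limit at equal totals:
    doubled smaller binomial(s=a+b, 1/2) tail, capped at 1."""
    s = a + b
    pmf = [math.comb(s, k) * 0.5 ** s for k in range(s + 1)]
    lower = sum(pmf[: a + 1])
    upper = sum(pmf[a:])
    return min(1.0, 2.0 * min(lower, upper))


def brute_force_cis_pairs(
    focal: dict[str, tuple[str, int, int, str]],
    elements: list[tuple[str, tuple[str, int, int]]],
    window_bp: int,
    side: str,
) -> set[tuple[str, str]]:
    """All-pairs (focal, element) attachment per the window-extension rule.

    Focal entries are (chrom, start, end, strand); elements (chrom, start,
    end).  Unknown strand counts as '+'.
    """
    out = set()
    for fid, (fc, fs, fe, strand) in focal.items():
        strand = strand if strand in ("+", "-") else "+"
        lo, hi = fs, fe
        left = side == "both" or (side == "upstream") == (strand == "+")
        right = side == "both" or (side == "downstream") == (strand == "+")
        if side == "both":
            left = right = True
        if left:
            lo = max(0, lo - window_bp)
        if right:
            hi = hi + window_bp
        for eid, (ec, es, ee) in elements:
            if ec == fc and es < hi and lo < ee:
                out.add((fid, eid))
    return out


def brute_force_peak_components(
    peaks: list[tuple[str, str, int, int]],
) -> list[tuple[str, int, int, frozenset[str]]]:
    """Connected components of the midpoint-match relation by all-pairs
    union-find.  Peaks are (peak_id, chrom, start, end)."""
    n = len(peaks)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def matched(i, j):
        _, ci, si, ei = peaks[i]
        _, cj, sj, ej = peaks[j]
        if ci != cj:
            return False
        mi, mj = (si + ei) // 2, (sj + ej) // 2
        return (sj <= mi < ej) or (si <= mj < ei)

    for i in range(n):
        for j in range(i + 1, n):
            if matched(i, j):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    comps = []
    for members in groups.values():
        chrom = peaks[members[0]][1]
        start = min(peaks[i][2] for i in members)
        end = max(peaks[i][3] for i in members)
        comps.append((chrom, start, end, frozenset(peaks[i][0] for i in members)))
    comps.sort(key=lambda c: (c[0], c[1], c[2]))
    return comps


def set_algebra_subset_counts(edge_sets: list[set]) -> dict[tuple[int, ...], int]:
    """Exclusive subset counts over the union, by direct set algebra."""
    union = set().union(*edge_sets)
    counts: dict[tuple[int, ...], int] = {}
    for e in union:
        key = tuple(i for i, s in enumerate(edge_sets) if e in s)
        counts[key] = counts.get(key, 0) + 1
    return counts


def aupr(labels: list[bool], scores: list[float]) -> float:
    """Area under the precision-recall curve (average precision form),
    computed by sorting and accumulating -- no library call."""
    order = sorted(range(len(scores)), key=lambda i: -scores[i])
    n_pos = sum(labels)
    tp = 0
    area = 0.0
    for rank, i in enumerate(order, start=1):
        if labels[i]:
            tp += 1
            area += tp / rank
    return area / n_pos if n_pos else 0.0
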