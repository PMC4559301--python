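"""Disease-class normalization of DMR genes and bootstrap-supported
hierarchical clustering of DMR methylation profiles.

Cluster support follows the multiscale-bootstrap construction: bootstrap
probabilities (BP) are collected at several resampling scales r (resample
ceil(r * n_samples) columns), the normal quantiles of 1 - BP are regressed
on (sqrt(r), 1/sqrt(r)) to estimate the signed distance v and curvature c
of the cluster boundary, and the approximately unbiased probability is
AU = 1 - Phi(v - c).  Clusters with AU >= 0.95 are flagged robust.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.45, 0.1), 2))


def disease_class_distribution(dmr_genes: Sequence[str],
                               gene_classes: Mapping[str, Sequence[str]],
                               class_sizes: Mapping[str, int]):
    """Per-class normalized DMR-gene counts plus the overall annotated fraction.

    normalized = (distinct DMR genes in class) / (total genes in class).
    Genes annotated to a class without a known size are skipped with a
    warning.  Returns (profile frame, fraction of DMR genes with any
    disease annotation).
    """
    for cls, size in class_sizes.items():
        if size <= 0:
            raise ValueError(f"class {cls} has non-positive size {size}")
    genes = sorted(set(dmr_genes))
    per_class: Dict[str, set] = {cls: set() for cls in class_sizes}
    annotated = set()
    for g in genes:
        for cls in gene_classes.get(g, ()):
            if cls not in class_sizes:
                warnings.warn(f"gene {g} mapped to unknown class {cls}; skipped")
                continue
            per_class[cls].add(g)
            annotated.add(g)
    rows = [(cls, len(members), class_sizes[cls],
             len(members) / class_sizes[cls])
            for cls, members in sorted(per_class.items())]
    profile = pd.DataFrame(rows, columns=["class", "dmr_gene_count",
                                          "class_total_genes", "normalized"])
    fraction = len(annotated) / len(genes) if genes else 0.0
    return profile, fraction


def zscore_rows(matrix: np.ndarray):
    """Median-centred row Z-scores: (x - row median) / row sd (n-1).

    Zero-sd rows are excluded; returns (standardized matrix, kept row
    indices, excluded row indices).
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 samples")
    med = np.median(x, axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    ok = sd[:, 0] > 0
    z = (x[ok] - med[ok]) / sd[ok]
    return z, np.flatnonzero(ok), np.flatnonzero(~ok)


def _cluster_sets(Z: np.ndarray, n: int) -> List[FrozenSet[int]]:
    """Leaf sets of every internal dendrogram node, in merge order."""
    members: Dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    out = []
    for k, (a, b, *_dummy) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n + k] = merged
        out.append(merged)
    return out


@dataclass
class ClusterResult:
    """Dendrogram with per-node multiscale-bootstrap support."""

    linkage_matrix: np.ndarray
    clusters: List[FrozenSet[int]]
    bp: np.ndarray           # bootstrap probability at scale closest to 1
    au: np.ndarray           # approximately unbiased probability
    scales: tuple
    n_boot: int
    seed: int
    robust_threshold: float = 0.95
    bp_by_scale: pd.DataFrame | None = None
    row_matrix: np.ndarray | None = None

    @property
    def robust(self) -> np.ndarray:
        return self.au >= self.robust_threshold


def cluster_with_bootstrap(matrix: np.ndarray, n_boot: int = 1000,
                           scales: Sequence[float] = DEFAULT_SCALES,
                           seed: int = 0, method: str = "average") -> ClusterResult:
    """Hierarchical clustering of rows (Euclidean, average linkage) with
    multiscale-bootstrap AU/BP support per internal node.

    Columns (samples) are resampled with replacement at each scale.
    Deterministic given the seed; refuses n_boot < 100 because the AU
    regression is unstable below that.
    """
    x = np.asarray(matrix, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need >= 3 rows to cluster")
    if n_boot < 100:
        raise ValueError("n_boot < 100: AU regression unstable, refusing")
    rng = np.random.default_rng([int(seed) % (2**31), 31])
    n_rows, n_cols = x.shape
    Z = linkage(x, method=method, metric="euclidean")
    clusters = _cluster_sets(Z, n_rows)
    counts = np.zeros((len(scales), len(clusters)))
    cluster_index = {c: i for i, c in enumerate(clusters)}
    for si, r in enumerate(scales):
        m = max(int(np.ceil(r * n_cols)), 2)
        for _ in range(n_boot):
            cols = rng.integers(0, n_cols, size=m)
            xb = x[:, cols]
            try:
                Zb = linkage(xb, method=method, metric="euclidean")
            except ValueError:
                continue
            for c in _cluster_sets(Zb, n_rows):
                i = cluster_index.get(c)
                if i is not None:
                    counts[si, i] += 1
    bp_by_scale = counts / n_boot
    eps = 1.0 / (2 * n_boot)
    au = np.empty(len(clusters))
    for i, c in enumerate(clusters):
        if len(c) == n_rows:
            au[i] = 1.0
            continue
        raw = bp_by_scale[:, i]
        # degenerate support: cluster present (absent) in every resample at
        # every scale carries no gradient information for the regression
        if np.all(raw >= 1 - eps):
            au[i] = 1.0
            continue
        if np.all(raw <= eps):
            au[i] = 0.0
            continue
        bp = np.clip(raw, eps, 1 - eps)
        z = stats.norm.ppf(1.0 - bp)
        sq = np.sqrt(np.asarray(scales))
        X = np.column_stack([sq, 1.0 / sq])
        # delta-method weights for the probit-transformed BP
        wts = n_boot * stats.norm.pdf(z) ** 2 / (bp * (1 - bp))
        W = np.diag(wts)
        try:
            coef = np.linalg.solve(X.T @ W @ X, X.T @ W @ z)
        except np.linalg.LinAlgError:
            coef = np.linalg.lstsq(X, z, rcond=None)[0]
        v, cc = coef
        au[i] = float(1.0 - stats.norm.cdf(v - cc))
    scale1 = int(np.argmin(np.abs(np.asarray(scales) - 1.0)))
    bp_frame = pd.DataFrame(bp_by_scale, index=list(scales))
    return ClusterResult(linkage_matrix=Z, clusters=clusters,
                         bp=bp_by_scale[scale1], au=au, scales=tuple(scales),
                         n_boot=n_boot, seed=seed, bp_by_scale=bp_frame,
                         row_matrix=x)
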