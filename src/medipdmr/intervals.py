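"""Permutation-based spatial association between interval sets and related
overlap statistics.

The association null repositions each query interval uniformly within its
own chromosome (length preserved, overlaps allowed) and compares the
observed Jaccard measure and relative-distance Kolmogorov-Smirnov statistic
to their permutation distributions with add-one empirical p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .core import (_overlap_bases_sorted, frame_midpoints, merge_intervals,
                   overlap_bases, overlaps_any, total_bases)
from ._stats import mann_whitney_u


def jaccard_measure(a: pd.DataFrame, b: pd.DataFrame) -> float:
    """Intersection bases / union bases of two interval sets (each merged)."""
    if len(a) == 0 and len(b) == 0:
        raise ValueError("Jaccard undefined for two empty interval sets")
    inter = overlap_bases(a, b)
    union = total_bases(a) + total_bases(b) - inter
    return inter / union if union else 0.0


def relative_distances(query: pd.DataFrame, reference: pd.DataFrame):
    """Midpoint-to-midpoint relative distances, uniform on [0, 0.5] under independence.

    For a query midpoint q between consecutive reference midpoints L <= q <= R:
    d = min(q - L, R - q) / (R - L).  Queries outside the flanked range are
    excluded; returns (distances, n_excluded).
    """
    ref_mids: Dict[str, np.ndarray] = {}
    for chrom, sub in reference.groupby("chrom", sort=False):
        mids = np.sort(frame_midpoints(sub).to_numpy(np.int64))
        if len(mids) >= 2:
            ref_mids[chrom] = mids
    if not ref_mids:
        raise ValueError("reference needs >= 2 midpoints on at least one chromosome")
    out = []
    excluded = 0
    for chrom, sub in query.groupby("chrom", sort=False):
        q = frame_midpoints(sub).to_numpy(np.int64)
        if chrom not in ref_mids:
            excluded += len(q)
            continue
        mids = ref_mids[chrom]
        inside = (q >= mids[0]) & (q <= mids[-1])
        excluded += int((~inside).sum())
        qi = q[inside]
        right = np.clip(np.searchsorted(mids, qi, side="left"), 1, len(mids) - 1)
        L, R = mids[right - 1], mids[right]
        d = np.minimum(qi - L, R - qi) / (R - L)
        out.append(d)
    dists = np.concatenate(out) if out else np.array([])
    return dists, excluded


@dataclass
class SpatialAssociation:
    """Permutation association result for one query/reference pair."""

    query_name: str
    reference_name: str
    jaccard_observed: float
    jaccard_p: float
    jaccard_relationship: str
    ks_statistic: float
    ks_p: float
    ks_relationship: str
    ks_p_analytic: float
    n_permutations: int
    seed: int


def _permute_intervals(rng, query: pd.DataFrame,
                       chrom_sizes: Mapping[str, int]) -> pd.DataFrame:
    lengths = (query["end"] - query["start"]).to_numpy(np.int64)
    sizes = query["chrom"].map(chrom_sizes).to_numpy(np.int64)
    if np.any(lengths > sizes):
        raise ValueError("interval longer than its chromosome")
    starts = (rng.random(len(query)) * (sizes - lengths + 1)).astype(np.int64)
    return pd.DataFrame({"chrom": query["chrom"].to_numpy(),
                         "start": starts, "end": starts + lengths})


def _merge_arrays(starts: np.ndarray, ends: np.ndarray):
    """Merge possibly-overlapping intervals given as arrays (one chromosome)."""
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    cummax = np.maximum.accumulate(e)
    new_group = np.concatenate([[True], s[1:] > cummax[:-1]])
    firsts = np.flatnonzero(new_group)
    return s[firsts], np.maximum.reduceat(e, firsts)


def _rel_dist_arrays(q_mids: np.ndarray, ref_mids: np.ndarray) -> np.ndarray:
    inside = (q_mids >= ref_mids[0]) & (q_mids <= ref_mids[-1])
    qi = q_mids[inside]
    right = np.clip(np.searchsorted(ref_mids, qi, side="left"), 1, len(ref_mids) - 1)
    L, R = ref_mids[right - 1], ref_mids[right]
    return np.minimum(qi - L, R - qi) / (R - L)


def _ks_stat_against_sorted(sample: np.ndarray, pool_sorted: np.ndarray) -> float:
    """Two-sample KS statistic of `sample` against a pre-sorted pool."""
    if len(sample) == 0:
        return 0.0
    s = np.sort(sample)
    n = len(s)
    f_pool = np.searchsorted(pool_sorted, s, side="right") / len(pool_sorted)
    i = np.arange(n)
    return float(np.maximum(f_pool - i / n, (i + 1) / n - f_pool).max())


def _two_sided_empirical_p(observed: float, null: np.ndarray) -> float:
    n = len(null)
    p_ge = (np.sum(null >= observed - 1e-15) + 1) / (n + 1)
    p_le = (np.sum(null <= observed + 1e-15) + 1) / (n + 1)
    return min(1.0, 2.0 * min(p_ge, p_le))


def permutation_association(query: pd.DataFrame, reference: pd.DataFrame,
                            chrom_sizes: Mapping[str, int], n_perm: int = 10_000,
                            seed: int = 0, query_name: str = "query",
                            reference_name: str = "reference") -> SpatialAssociation:
    """Jaccard and relative-distance KS association with a permutation null.

    Query intervals are repositioned uniformly within their own chromosome
    (lengths preserved, overlaps permitted).  Empirical p-values use the
    add-one rule (r + 1) / (n + 1); relationships are labelled positive or
    negative by comparing the observed statistic to the permutation mean.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng([int(seed) % (2**31), 17])
    ref_merged = merge_intervals(reference)
    jac_obs = jaccard_measure(query, ref_merged)
    d_obs, _ = relative_distances(query, ref_merged)

    # fast per-chromosome array path for the permutation loop
    chroms = sorted(set(query["chrom"]))
    q_lengths = {}
    ref_arrays = {}
    ref_mid_arrays = {}
    ref_len_total = 0
    for chrom, sub in ref_merged.groupby("chrom", sort=False):
        rs = sub["start"].to_numpy(np.int64)
        re_ = sub["end"].to_numpy(np.int64)
        ref_arrays[chrom] = (rs, re_)
        ref_len_total += int((re_ - rs).sum())
        mids = np.sort((rs + re_) // 2)
        if len(mids) >= 2:
            ref_mid_arrays[chrom] = mids
    for chrom in chroms:
        lens = (query.loc[query["chrom"] == chrom, "end"]
                - query.loc[query["chrom"] == chrom, "start"]).to_numpy(np.int64)
        if chrom not in chrom_sizes:
            raise KeyError(f"no chromosome size for {chrom}")
        if np.any(lens > chrom_sizes[chrom]):
            raise ValueError("interval longer than its chromosome")
        q_lengths[chrom] = lens

    jac_null = np.empty(n_perm)
    d_perm_all = []
    for i in range(n_perm):
        inter = 0
        q_len_total = 0
        d_parts = []
        for chrom in chroms:
            lens = q_lengths[chrom]
            starts = (rng.random(len(lens))
                      * (chrom_sizes[chrom] - lens + 1)).astype(np.int64)
            ms, me = _merge_arrays(starts, starts + lens)
            q_len_total += int((me - ms).sum())
            if chrom in ref_arrays:
                rs, re_ = ref_arrays[chrom]
                inter += _overlap_bases_sorted(ms, me, rs, re_)
            if chrom in ref_mid_arrays:
                d_parts.append(_rel_dist_arrays((2 * starts + lens) // 2,
                                                ref_mid_arrays[chrom]))
        union = q_len_total + ref_len_total - inter
        jac_null[i] = inter / union if union else 0.0
        d_perm_all.append(np.concatenate(d_parts) if d_parts else np.array([]))
    pooled = np.sort(np.concatenate(d_perm_all)) if d_perm_all else np.array([0.25])
    if len(pooled) == 0:
        pooled = np.array([0.25])
    ks_obs = _ks_stat_against_sorted(d_obs, pooled) if len(d_obs) else 0.0
    ks_null = np.array([_ks_stat_against_sorted(d, pooled) for d in d_perm_all])
    jac_p = _two_sided_empirical_p(jac_obs, jac_null)
    ks_p = (np.sum(ks_null >= ks_obs - 1e-15) + 1) / (n_perm + 1)
    ks_analytic = (stats.kstest(d_obs * 2.0, "uniform").pvalue
                   if len(d_obs) else 1.0)
    jac_rel = ("positive" if jac_obs > jac_null.mean()
               else "negative" if jac_obs < jac_null.mean() else "none")
    d_rel = "none"
    if len(d_obs):
        d_rel = "positive" if d_obs.mean() < pooled.mean() else "negative"
    return SpatialAssociation(
        query_name=query_name, reference_name=reference_name,
        jaccard_observed=jac_obs, jaccard_p=float(jac_p),
        jaccard_relationship=jac_rel,
        ks_statistic=float(ks_obs), ks_p=float(ks_p), ks_relationship=d_rel,
        ks_p_analytic=float(ks_analytic),
        n_permutations=n_perm, seed=seed,
    )


def overlap_composition(dmrs: pd.DataFrame, annotation) -> dict:
    """Fraction of DMRs overlapping each feature class (>= 1 bp; classes not exclusive).

    Returns {'CpGi': f, 'gene': f, 'repeat': f, 'repeat_families': {...}} where
    the family breakdown is among repeat-overlapping DMRs.
    """
    n = len(dmrs)
    out: dict = {"CpGi": 0.0, "gene": 0.0, "repeat": 0.0, "repeat_families": {}}
    if n == 0:
        return out
    if len(annotation.cpg_islands):
        out["CpGi"] = float(overlaps_any(dmrs, annotation.cpg_islands).mean())
    if len(annotation.genes):
        out["gene"] = float(overlaps_any(dmrs, annotation.genes).mean())
    if len(annotation.repeats):
        rep_hit = overlaps_any(dmrs, annotation.repeats)
        out["repeat"] = float(rep_hit.mean())
        n_rep = int(rep_hit.sum())
        if n_rep:
            sub = dmrs.loc[rep_hit]
            for cls, csub in annotation.repeats.groupby("name", sort=True):
                out["repeat_families"][cls] = float(overlaps_any(sub, csub).sum() / n_rep)
    return out


def region_set_differential(matrix, region_sets: Mapping[str, pd.DataFrame]):
    """Per-region Hi-Lo mean normalized difference, compared across two sets.

    For each region: mean over member windows of (mean normalized Hi - mean
    normalized Lo).  With exactly two non-empty sets, a two-sided
    Mann-Whitney U over per-region differences is reported; sets with fewer
    than 2 covered regions make the test refuse (p = None).
    """
    if matrix.normalized is None:
        raise ValueError("matrix must be normalized first")
    is_hi = (matrix.samples["group"] == "Hi").to_numpy()
    diff_w = (matrix.normalized[:, is_hi].mean(axis=1)
              - matrix.normalized[:, ~is_hi].mean(axis=1))
    per_set: Dict[str, np.ndarray] = {}
    empty = []
    for name, regions in region_sets.items():
        vals = []
        for _, reg in regions.iterrows():
            hit = ((matrix.windows["chrom"] == reg["chrom"])
                   & (matrix.windows["start"] < reg["end"])
                   & (matrix.windows["end"] > reg["start"])).to_numpy()
            if hit.any():
                vals.append(diff_w[hit].mean())
        if vals:
            per_set[name] = np.asarray(vals)
        else:
            empty.append(name)
    report = {"per_set_mean_difference": {k: float(v.mean()) for k, v in per_set.items()},
              "per_set_differences": per_set, "empty_sets": empty,
              "u": None, "p": None}
    names = list(per_set)
    if len(names) == 2:
        a, b = per_set[names[0]], per_set[names[1]]
        if min(len(a), len(b)) >= 2:
            u, p = mann_whitney_u(a, b)
            report["u"], report["p"] = float(u), float(p)
    return report


def overlap_with_published_dmrs(dmrs: pd.DataFrame, external_regions: pd.DataFrame,
                                external_genes, nearest_genes=None):
    """Counts of DMRs overlapping an external region set, and of shared nearest genes."""
    region_overlaps = int(overlaps_any(dmrs, external_regions).sum()) \
        if len(external_regions) else 0
    genes = (set(dmrs["nearest_gene"].dropna()) if nearest_genes is None
             else set(nearest_genes))
    gene_overlaps = len(genes & set(external_genes))
    return region_overlaps, gene_overlaps


def _expand(dmrs: pd.DataFrame, size: int) -> pd.DataFrame:
    """Symmetric expansion by size/2 around the midpoint; size 0 keeps the window."""
    if size == 0:
        return dmrs.loc[:, ["chrom", "start", "end"]].copy()
    mids = frame_midpoints(dmrs)
    half = size // 2
    return pd.DataFrame({"chrom": dmrs["chrom"],
                         "start": np.maximum(mids - half, 0),
                         "end": mids + half})


def tfbs_progressive_enrichment(hypo_top: pd.DataFrame, hyper_top: pd.DataFrame,
                                peaks_per_factor: Mapping[str, pd.DataFrame],
                                window_sizes=(0, 1000, 2000, 5000)) -> pd.DataFrame:
    """Hypo-vs-hyper TFBS overlap representation at progressive window sizes.

    Each top DMR is expanded symmetrically; representation % = hypo
    overlaps / (hypo + hyper overlaps) x 100; a 2x2 Pearson chi-square
    (1 df, no continuity correction) of overlapping counts versus set sizes
    tests departure from the 50% expectation for equal-size sets.
    """
    rows = []
    for factor, peaks in peaks_per_factor.items():
        merged = merge_intervals(peaks)
        for size in window_sizes:
            h_hit = int(overlaps_any(_expand(hypo_top, size), merged).sum())
            y_hit = int(overlaps_any(_expand(hyper_top, size), merged).sum())
            total = h_hit + y_hit
            if total == 0:
                rows.append((factor, size, h_hit, y_hit, np.nan, np.nan))
                continue
            rep = 100.0 * h_hit / total
            a, b = h_hit, y_hit
            c, d = len(hypo_top) - h_hit, len(hyper_top) - y_hit
            denom = (a + b) * (c + d) * (a + c) * (b + d)
            if denom == 0:
                chi_p = 1.0  # degenerate margin: no departure measurable
            else:
                chi2 = (a + b + c + d) * (a * d - b * c) ** 2 / denom
                chi_p = float(stats.chi2.sf(chi2, df=1))
            rows.append((factor, size, h_hit, y_hit, rep, chi_p))
    return pd.DataFrame(rows, columns=["factor", "window_size", "hypo_overlaps",
                                       "hyper_overlaps", "representation_pct", "p"])
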