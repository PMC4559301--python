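"""Negative-binomial GLM differential methylation between Hi and Lo groups.

Counts in window w for sample s are modelled as NB(mu_ws, phi_w) with
log mu_ws = offset_s + x_s' beta_w, where the design carries an intercept,
the Hi/Lo group indicator and gender / IP-batch nuisance covariates.  The
per-window dispersion phi_w is estimated by Cox-Reid adjusted profile
likelihood and shrunk toward the common value by weighted likelihood
("tagwise" dispersion).  The group coefficient is tested by a 1-df
likelihood-ratio test; p-values are Benjamini-Hochberg adjusted.

Normalization enters as per-sample log offsets so that dispersion and
testing operate on raw integer counts (the statistically coherent reading
of fitting count GLMs after full-quantile normalization).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .core import frame_midpoints
from .windows import WindowCountMatrix, normalization_offsets

_MAX_IRLS = 100
_DEV_TOL = 1e-8
_ETA_CLIP = 30.0


def build_design(samples: pd.DataFrame):
    """Design matrix: intercept + group + gender + batch (reference coded).

    Returns (X, column_names) with X of full column rank.  A factor with a
    single observed level is omitted with a warning; a covariate aliased
    with columns already in the design (e.g. batch identical to group)
    raises, naming the aliased columns.
    """
    groups = samples["group"].to_numpy()
    if min((groups == "Hi").sum(), (groups == "Lo").sum()) < 2:
        raise ValueError("need at least 2 samples in each of Hi and Lo")
    n = len(samples)
    cols = [np.ones(n)]
    names = ["intercept"]
    cols.append((groups == "Hi").astype(float))
    names.append("group_Hi")

    def add_factor(values, label):
        nonlocal cols, names
        levels = sorted(pd.unique(values))
        if len(levels) < 2:
            warnings.warn(f"factor {label} has a single level; omitted from design")
            return
        for lev in levels[1:]:
            cand = (values == lev).astype(float)
            X_try = np.column_stack(cols + [cand])
            if np.linalg.matrix_rank(X_try) <= np.linalg.matrix_rank(np.column_stack(cols)):
                raise ValueError(
                    f"design column {label}_{lev} is aliased with existing columns "
                    f"{names}; confounded design"
                )
            cols.append(cand)
            names.append(f"{label}_{lev}")

    if "gender" in samples.columns:
        add_factor(samples["gender"].to_numpy(), "gender")
    if "ip_batch" in samples.columns:
        add_factor(samples["ip_batch"].to_numpy(), "batch")
    X = np.column_stack(cols)
    return X, names


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi) -> np.ndarray:
    """Per-window NB log-likelihood summed over samples; phi scalar or (G,1)."""
    phi = np.maximum(np.asarray(phi, dtype=float), 1e-12)
    if phi.ndim == 1:
        phi = phi[:, None]
    r = 1.0 / phi
    ll = (special.gammaln(y + r) - special.gammaln(r) - special.gammaln(y + 1.0)
          + y * np.log(np.maximum(phi * mu, 1e-300) / (1.0 + phi * mu))
          - r * np.log1p(phi * mu))
    return ll.sum(axis=1)


def _irls(y: np.ndarray, X: np.ndarray, offset: np.ndarray, phi,
          max_iter: int = _MAX_IRLS, tol: float = _DEV_TOL):
    """Batched IRLS for NB GLMs with log link across G windows.

    y: (G, n); X: (n, p); offset: (n,) or (G, n); phi: scalar or (G,).
    Returns (beta (G, p), mu (G, n), converged (G,)).
    """
    G, n = y.shape
    p = X.shape[1]
    phi_arr = np.broadcast_to(np.asarray(phi, dtype=float), (G,)).reshape(G, 1)
    off = np.broadcast_to(offset, (G, n))
    # initialise from weighted least squares on log(y + 0.125)
    z0 = np.log(y + 0.125) - off
    beta, *_ = np.linalg.lstsq(X, z0.T, rcond=None)
    beta = beta.T
    ll_old = np.full(G, -np.inf)
    converged = np.zeros(G, dtype=bool)
    mu = None
    for _ in range(max_iter):
        eta = np.clip(beta @ X.T + off, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        W = mu / (1.0 + phi_arr * mu)
        z = (eta - off) + (y - mu) / mu
        A = np.einsum("ni,gn,nj->gij", X, W, X)
        A += 1e-10 * np.eye(p)
        b = np.einsum("gn,gn,ni->gi", W, z, X)
        active = ~converged
        try:
            beta_new = np.linalg.solve(A, b[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(
                A.reshape(-1, p), b.reshape(-1, 1), rcond=None
            )[0].reshape(G, p)
        beta[active] = beta_new[active]
        eta = np.clip(beta @ X.T + off, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        ll = _nb_loglik(y, mu, phi_arr[:, 0])
        converged |= np.abs(ll - ll_old) < tol * (np.abs(ll) + 1.0)
        ll_old = ll
        if converged.all():
            break
    return beta, mu, converged


def _cox_reid_apl(y: np.ndarray, X: np.ndarray, offset: np.ndarray, phi) -> np.ndarray:
    """Per-window Cox-Reid adjusted profile log-likelihood at dispersion phi."""
    G, n = y.shape
    phi_arr = np.broadcast_to(np.asarray(phi, dtype=float), (G,))
    beta, mu, _ = _irls(y, X, offset, phi_arr, max_iter=50)
    ll = _nb_loglik(y, mu, phi_arr)
    W = mu / (1.0 + phi_arr[:, None] * mu)
    A = np.einsum("ni,gn,nj->gij", X, W, X) + 1e-10 * np.eye(X.shape[1])
    _, logdet = np.linalg.slogdet(A)
    return ll - 0.5 * logdet


@dataclass
class DispersionEstimate:
    """Common and per-window (tagwise) NB dispersions with shrinkage weight."""

    common: float
    tagwise: np.ndarray
    prior_df: float
    unshrunk: Optional[np.ndarray] = None


_PHI_GRID = np.exp(np.linspace(np.log(1e-6), np.log(5.0), 36))


def estimate_dispersions(matrix: WindowCountMatrix, design: np.ndarray,
                         prior_df: float = 10.0,
                         offsets: Optional[np.ndarray] = None) -> DispersionEstimate:
    """Estimate common and tagwise dispersions by Cox-Reid APL.

    The common phi maximizes the summed APL over windows; each tagwise
    phi_w maximizes APL_w + prior_df * mean-per-window APL (weighted
    likelihood shrinkage toward the common value).
    """
    y = matrix.raw
    if not np.issubdtype(y.dtype, np.integer):
        if not np.allclose(y, np.round(y)):
            raise ValueError("dispersion estimation requires raw integer counts; "
                             "pass normalization as offsets")
        y = np.round(y).astype(np.int64)
    y = y.astype(float)
    if offsets is None:
        offsets = (normalization_offsets(matrix) if matrix.normalized is not None
                   else np.zeros(matrix.n_samples))
    n, p = design.shape
    if n - p < 2:
        raise ValueError("need at least 2 residual degrees of freedom")
    G = y.shape[0]
    apl = np.empty((G, len(_PHI_GRID)))
    for k, phi in enumerate(_PHI_GRID):
        apl[:, k] = _cox_reid_apl(y, design, offsets, phi)
    total = apl.sum(axis=0)
    k_best = int(np.argmax(total))
    lo = _PHI_GRID[max(k_best - 1, 0)]
    hi = _PHI_GRID[min(k_best + 1, len(_PHI_GRID) - 1)]
    if lo == hi:
        common = float(_PHI_GRID[k_best])
    else:
        res = optimize.minimize_scalar(
            lambda lphi: -_cox_reid_apl(y, design, offsets, np.exp(lphi)).sum(),
            bounds=(np.log(lo), np.log(hi)), method="bounded",
            options={"xatol": 1e-3},
        )
        common = float(np.exp(res.x))
    mean_apl = apl.mean(axis=0)
    shrunk_obj = apl + prior_df * mean_apl[None, :]
    tagwise = _interp_argmax(shrunk_obj)
    unshrunk = _interp_argmax(apl)
    return DispersionEstimate(common=common, tagwise=tagwise,
                              prior_df=prior_df, unshrunk=unshrunk)


def _interp_argmax(obj: np.ndarray) -> np.ndarray:
    """Per-row argmax over the phi grid with log-space quadratic refinement."""
    k = np.argmax(obj, axis=1)
    lphi = np.log(_PHI_GRID)
    out = lphi[k].copy()
    interior = (k > 0) & (k < len(_PHI_GRID) - 1)
    ki = k[interior]
    rows = np.where(interior)[0]
    y0 = obj[rows, ki - 1]
    y1 = obj[rows, ki]
    y2 = obj[rows, ki + 1]
    denom = (y0 - 2 * y1 + y2)
    with np.errstate(divide="ignore", invalid="ignore"):
        shift = 0.5 * (y0 - y2) / denom
    shift = np.where(np.abs(denom) > 1e-12, np.clip(shift, -1, 1), 0.0)
    step = lphi[1] - lphi[0]
    out[rows] = lphi[ki] + shift * step
    return np.exp(out)


def test_windows(matrix: WindowCountMatrix, design: np.ndarray,
                 dispersions: DispersionEstimate,
                 offsets: Optional[np.ndarray] = None,
                 group_col: int = 1) -> pd.DataFrame:
    """Per-window NB GLM likelihood-ratio test of the group coefficient.

    Returns a DMR table with columns chrom/start/end, log2fc (Hi relative
    to Lo), direction, p, q, rank and convergence flag, ranked by p.
    Non-converging windows are flagged with p set to 1.
    """
    y = matrix.raw.astype(float)
    if offsets is None:
        offsets = (normalization_offsets(matrix) if matrix.normalized is not None
                   else np.zeros(matrix.n_samples))
    phi = dispersions.tagwise
    X_full = design
    X_red = np.delete(design, group_col, axis=1)
    beta_f, mu_f, conv_f = _irls(y, X_full, offsets, phi)
    _, mu_r, conv_r = _irls(y, X_red, offsets, phi)
    ll_f = _nb_loglik(y, mu_f, phi)
    ll_r = _nb_loglik(y, mu_r, phi)
    lrt = np.maximum(2.0 * (ll_f - ll_r), 0.0)
    p = stats.chi2.sf(lrt, df=1)
    converged = conv_f & conv_r
    n_fail = int((~converged).sum())
    if n_fail:
        warnings.warn(f"{n_fail} windows failed to converge; their p set to 1")
        p = np.where(converged, p, 1.0)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    log2fc = beta_f[:, group_col] / np.log(2.0)
    out = matrix.windows.copy()
    out["log2fc"] = log2fc
    out["direction"] = np.where(log2fc < 0, "hypo", "hyper")
    out["p"] = p
    out["q"] = bh_adjust(p)
    out["converged"] = converged
    out["rank"] = stats.rankdata(p, method="ordinal").astype(int)
    return out.sort_values("rank").reset_index(drop=True)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg FDR adjustment: q_i = min_{p_j >= p_i} n p_j / rank_j, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def annotate_nearest_gene(dmrs: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Annotate each DMR with the gene whose TSS is closest to the window midpoint.

    TSS is the interval start for '+' genes and the end for '-' genes; ties
    in distance are broken by lexicographic gene id; chromosomes without
    genes yield nearest_gene = None.
    """
    tss = np.where(genes["strand"] == "-", genes["end"], genes["start"]).astype(np.int64)
    gframe = pd.DataFrame({"chrom": genes["chrom"], "tss": tss, "name": genes["name"]})
    out = dmrs.copy()
    out["nearest_gene"] = None
    out["tss_distance"] = np.nan
    mids = frame_midpoints(dmrs).to_numpy(np.int64)
    for chrom, gsub in gframe.groupby("chrom", sort=False):
        mask = (dmrs["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        g_tss = gsub["tss"].to_numpy()
        g_ids = gsub["name"].to_numpy()
        d = np.abs(mids[mask][:, None] - g_tss[None, :])
        best = []
        for row in d:
            mind = row.min()
            cands = g_ids[row == mind]
            best.append(min(cands))
        best = np.asarray(best, dtype=object)
        dist = d.min(axis=1)
        out.loc[mask, "nearest_gene"] = best
        out.loc[mask, "tss_distance"] = dist
    return out


def direction_proportion_test(subset: pd.DataFrame,
                              background_hypo_fraction: float = 0.5):
    """Two-sided exact binomial test of the hypo/hyper split in a DMR subset.

    Returns (n_hypo, n_hyper, p) against the expected hypo fraction.
    """
    if len(subset) == 0:
        raise ValueError("empty DMR subset")
    n_hypo = int((subset["direction"] == "hypo").sum())
    n_hyper = len(subset) - n_hypo
    res = stats.binomtest(n_hypo, n_hypo + n_hyper, background_hypo_fraction,
                          alternative="two-sided")
    return n_hypo, n_hyper, float(res.pvalue)
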