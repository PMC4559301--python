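"""Genetic-confounding checks on DMR-proximal SNPs.

Assigns SNPs to DMR-centred windows, tests per-SNP allele-count association
with the Hi/Lo grouping, quantifies overrepresentation of
methylation-site-affecting substitution classes, and correlates relative
allele frequency with differential methylation.

CpG gain/loss classification: C/T and G/A substitutions destroy a
methylatable CpG context, T/C and A/G create one; flanking-base context is
deliberately ignored (not recoverable from a genotype table alone).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import CPG_AFFECTING

_LOSS_CLASSES = {"C/T", "G/A"}
_GAIN_CLASSES = {"T/C", "A/G"}


def assign_snps_to_dmrs(snps: pd.DataFrame, dmrs: pd.DataFrame,
                        span: int = 900):
    """Map each SNP to every DMR whose midpoint lies within span/2 of it.

    Returns (mapping frame with snp_id / dmr_index columns, n_dropped).
    A SNP equidistant to two DMR midpoints is assigned to both.
    """
    if span % 2:
        raise ValueError("span must be even")
    radius = span // 2
    rows = []
    mids = ((dmrs["start"] + dmrs["end"]) // 2).to_numpy(np.int64)
    for chrom, dsub in dmrs.groupby("chrom", sort=False):
        m = mids[dsub.index.to_numpy()]
        order = np.argsort(m)
        m_sorted = m[order]
        d_idx_sorted = dsub.index.to_numpy()[order]
        ssub = snps[snps["chrom"] == chrom]
        pos = ssub["pos"].to_numpy(np.int64)
        # DMR midpoints within [pos - radius, pos + radius] inclusive
        lo = np.searchsorted(m_sorted, pos - radius, side="left")
        hi = np.searchsorted(m_sorted, pos + radius, side="right")
        for snp_row, l, h in zip(ssub.itertuples(), lo, hi):
            for k in range(l, h):
                rows.append((snp_row.snp_id, int(d_idx_sorted[k])))
    mapping = pd.DataFrame(rows, columns=["snp_id", "dmr_index"])
    n_dropped = int(len(set(snps["snp_id"]) - set(mapping["snp_id"])))
    return mapping, n_dropped


def allele_class_overrepresentation(snps: pd.DataFrame,
                                    background: Mapping[str, float]) -> dict:
    """Observed/background frequency ratios of the 12 substitution classes.

    Also reports the aggregate ratio over the CpG-affecting set
    {C/T, G/A, T/C, A/G}.  Background frequencies must sum to 1.
    """
    if len(snps) == 0:
        raise ValueError("empty SNP set")
    tot_bg = sum(background.values())
    if not np.isclose(tot_bg, 1.0, atol=1e-6):
        raise ValueError(f"background frequencies sum to {tot_bg}, not 1")
    obs = snps["substitution_class"].value_counts(normalize=True)
    ratios = {}
    flagged = []
    for cls, bg in background.items():
        o = float(obs.get(cls, 0.0))
        if bg == 0:
            ratios[cls] = np.inf if o > 0 else np.nan
            if o > 0:
                flagged.append(cls)
        else:
            ratios[cls] = o / bg
    cpg_obs = sum(float(obs.get(c, 0.0)) for c in CPG_AFFECTING)
    cpg_bg = sum(background.get(c, 0.0) for c in CPG_AFFECTING)
    return {"per_class": ratios,
            "cpg_affecting_ratio": cpg_obs / cpg_bg if cpg_bg else np.inf,
            "zero_background_classes": flagged}


def group_association(genotypes: pd.DataFrame, dosages: np.ndarray,
                      samples: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Per-SNP allele-count association with the Hi/Lo grouping.

    Each SNP's 2x2 table (ref/alt allele counts x group) is tested by
    Pearson chi-square, falling back to Fisher's exact test when any
    expected cell is < 5.  The genome-wide line is Bonferroni:
    alpha / n_tested.  Monomorphic SNPs are skipped and counted.
    """
    is_hi = (samples["group"] == "Hi").to_numpy()
    if is_hi.all() or not is_hi.any():
        raise ValueError("both groups must be represented")
    rows = []
    n_skipped = 0
    for i, snp in enumerate(genotypes.itertuples()):
        dos = dosages[i]
        ok = dos >= 0
        alt_hi = int(dos[ok & is_hi].sum())
        alt_lo = int(dos[ok & ~is_hi].sum())
        ref_hi = int(2 * (ok & is_hi).sum() - alt_hi)
        ref_lo = int(2 * (ok & ~is_hi).sum() - alt_lo)
        table = np.array([[alt_hi, alt_lo], [ref_hi, ref_lo]])
        if table.sum(axis=1).min() == 0:
            n_skipped += 1
            continue
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        if expected.min() < 5:
            _, p = stats.fisher_exact(table)
            method = "fisher"
        else:
            chi2, p, *_ = stats.chi2_contingency(table, correction=False)
            method = "chi2"
        rows.append((snp.snp_id, snp.chrom, snp.pos, alt_hi, alt_lo,
                     float(p), method))
    table_df = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "alt_hi",
                                           "alt_lo", "p", "method"])
    threshold = alpha / len(table_df) if len(table_df) else np.nan
    table_df["significant"] = table_df["p"] < threshold
    return {"per_snp": table_df, "bonferroni_threshold": threshold,
            "n_significant": int(table_df["significant"].sum()),
            "n_skipped_monomorphic": n_skipped}


def classify_cpg_effect(ref: str, alt: str) -> str:
    """'loss', 'gain' or 'neutral' effect of the alt allele on CpG sites."""
    cls = f"{ref}/{alt}"
    if cls in _LOSS_CLASSES:
        return "loss"
    if cls in _GAIN_CLASSES:
        return "gain"
    return "neutral"


def maf_methylation_correlation(genotypes: pd.DataFrame, dosages: np.ndarray,
                                samples: pd.DataFrame, dmrs: pd.DataFrame,
                                mapping: pd.DataFrame,
                                min_stratum: int = 3) -> pd.DataFrame:
    """Pearson correlation of relative allele frequency vs DMR log2fc,
    stratified by (CpG gain/loss) x (hypo/hyper).

    Relative frequency per SNP = alt-allele frequency in Hi minus Lo; each
    SNP contributes once per mapped DMR.  Strata with fewer than
    ``min_stratum`` SNPs are omitted.
    """
    is_hi = (samples["group"] == "Hi").to_numpy()
    snp_index = {sid: i for i, sid in enumerate(genotypes["snp_id"])}
    rel_freq = np.array([
        dosages[i][is_hi & (dosages[i] >= 0)].mean() / 2.0
        - dosages[i][~is_hi & (dosages[i] >= 0)].mean() / 2.0
        for i in range(len(genotypes))
    ])
    effects = genotypes.apply(lambda r: classify_cpg_effect(r["ref"], r["alt"]),
                              axis=1).to_numpy()
    rows = []
    for _, m in mapping.iterrows():
        i = snp_index[m["snp_id"]]
        dmr = dmrs.loc[m["dmr_index"]]
        rows.append((effects[i], dmr["direction"], rel_freq[i], dmr["log2fc"]))
    obs = pd.DataFrame(rows, columns=["cpg_effect", "direction",
                                      "relative_freq", "log2fc"])
    out = []
    for (eff, direction), sub in obs.groupby(["cpg_effect", "direction"]):
        if eff == "neutral" or len(sub) < min_stratum:
            continue
        if sub["relative_freq"].std() == 0 or sub["log2fc"].std() == 0:
            continue
        r, p = stats.pearsonr(sub["relative_freq"], sub["log2fc"])
        out.append((eff, direction, len(sub), float(r), float(r**2), float(p)))
    return pd.DataFrame(out, columns=["cpg_effect", "direction", "n",
                                      "r", "r2", "p"])
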