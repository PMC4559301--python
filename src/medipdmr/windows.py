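"""Window tiling, fragment counting, relH CpG-enrichment QC, filtering and
full-quantile normalization of MeDIP-seq count matrices.

The analysis unit is a fixed-width genomic window (default 300 bp).  Counts
are fragment midpoints per window; normalization equalizes the count
distribution across samples (full-quantile), after which every sample
column shares the mean order-statistic vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

from .core import validate_intervals

CORTISOL_THRESHOLD = 8.9  # fmol/mg; Hi group strictly above


@dataclass
class WindowCountMatrix:
    """Fixed-width window x sample counts plus optional normalized values.

    ``windows`` is an interval frame (chrom, start, end) of uniform width,
    ``raw`` an integer (n_windows, n_samples) array, ``samples`` a sample
    sheet with columns sample_id, group, gender, ip_batch and optionally
    hair_cortisol.
    """

    windows: pd.DataFrame
    raw: np.ndarray
    samples: pd.DataFrame
    normalized: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        widths = (self.windows["end"] - self.windows["start"]).unique()
        if len(widths) > 1:
            raise ValueError(f"windows of mixed widths: {sorted(widths)}")
        if self.raw.shape != (len(self.windows), len(self.samples)):
            raise ValueError("raw count matrix shape does not match windows x samples")
        if np.any(self.raw < 0):
            raise ValueError("negative raw counts")

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def validate_sample_sheet(samples: pd.DataFrame) -> None:
    """Check group labels and, when cortisol is present, the grouping rule."""
    if not set(samples["group"]) <= {"Hi", "Lo"}:
        raise ValueError("group must be 'Hi' or 'Lo'")
    if "hair_cortisol" in samples.columns and samples["hair_cortisol"].notna().all():
        hi = samples["hair_cortisol"] > CORTISOL_THRESHOLD
        if not (hi == (samples["group"] == "Hi")).all():
            raise ValueError(
                f"group inconsistent with hair cortisol threshold {CORTISOL_THRESHOLD} fmol/mg"
            )


def tile_windows(chrom_sizes: Mapping[str, int], width: int = 300) -> pd.DataFrame:
    """Tile consecutive non-overlapping windows; trailing partial window dropped."""
    if width <= 0:
        raise ValueError("width must be positive")
    rows = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        if size <= 0:
            raise ValueError(f"non-positive size for {chrom}")
        n = size // width
        starts = np.arange(n, dtype=np.int64) * width
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + width}))
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return pd.concat(rows, ignore_index=True)


def count_fragments(
    fragments: Mapping[str, pd.DataFrame],
    windows: pd.DataFrame,
    samples: pd.DataFrame,
) -> WindowCountMatrix:
    """Count fragment midpoints per window for each sample.

    A fragment lands in the window containing floor((start+end)/2); fragments
    whose midpoint falls beyond the last full window on a chromosome are
    discarded (counted in ``meta['discarded']``).
    """
    width = int((windows["end"] - windows["start"]).iloc[0]) if len(windows) else 0
    # windows are contiguous from 0 per chromosome, so index = midpoint // width
    n_per_chrom = windows.groupby("chrom", sort=False).size()
    offsets: Dict[str, int] = {}
    acc = 0
    for chrom, n in n_per_chrom.items():
        offsets[chrom] = acc
        acc += int(n)
    raw = np.zeros((len(windows), len(samples)), dtype=np.int64)
    discarded = {}
    for j, sid in enumerate(samples["sample_id"]):
        frags = fragments[sid]
        validate_intervals(frags, what=f"fragment for sample {sid}")
        lost = 0
        for chrom, sub in frags.groupby("chrom", sort=False):
            if chrom not in offsets:
                raise ValueError(f"fragment chromosome {chrom} absent from windows")
            mids = ((sub["start"].to_numpy(np.int64) + sub["end"].to_numpy(np.int64)) // 2)
            idx = mids // width
            ok = idx < n_per_chrom[chrom]
            lost += int((~ok).sum())
            counts = np.bincount(idx[ok], minlength=n_per_chrom[chrom])
            base = offsets[chrom]
            raw[base : base + n_per_chrom[chrom], j] += counts
        discarded[sid] = lost
    return WindowCountMatrix(windows=windows.reset_index(drop=True), raw=raw,
                             samples=samples.reset_index(drop=True),
                             meta={"discarded": discarded})


def _cpg_prefix(seq: str) -> np.ndarray:
    """Prefix sums of CpG-dinucleotide start indicators for one chromosome."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_cg = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
    return np.concatenate([[0], np.cumsum(is_cg)])


def relh_score(fragments: pd.DataFrame, genome: Mapping[str, str],
               qc_threshold: float = 2.0):
    """Relative CpG enrichment of fragment footprints versus the genome.

    relH = (CpGs within fragments / fragment bases) / (genome CpGs / genome
    bases).  Overlapping fragments double-count (enrichment, not coverage,
    semantics).  Returns (score, passes_qc) with pass <=> score > threshold,
    the immunoprecipitation-efficiency QC rule.
    """
    validate_intervals(fragments, what="fragment")
    gen_cpg = sum(seq.count("CG") for seq in genome.values())
    gen_bases = sum(len(seq) for seq in genome.values())
    if gen_cpg == 0:
        raise ZeroDivisionError("genome contains no CpG dinucleotides; relH undefined")
    frag_cpg = 0
    frag_bases = 0
    for chrom, sub in fragments.groupby("chrom", sort=False):
        if chrom not in genome:
            raise KeyError(f"no genome sequence for chromosome {chrom}")
        pref = _cpg_prefix(genome[chrom])
        starts = sub["start"].to_numpy(np.int64)
        ends = np.minimum(sub["end"].to_numpy(np.int64), len(genome[chrom]))
        # CpG start positions strictly inside [start, end-1)
        frag_cpg += int((pref[np.maximum(ends - 1, starts)] - pref[starts]).sum())
        frag_bases += int((ends - starts).sum())
    score = (frag_cpg / frag_bases) / (gen_cpg / gen_bases)
    return score, score > qc_threshold


def filter_windows(matrix: WindowCountMatrix, min_count: int = 5,
                   min_fraction: float = 0.5) -> WindowCountMatrix:
    """Keep windows with count > min_count (strict) in >= ceil(min_fraction * n) samples."""
    need = int(np.ceil(min_fraction * matrix.n_samples))
    keep = (matrix.raw > min_count).sum(axis=1) >= need
    return WindowCountMatrix(
        windows=matrix.windows.loc[keep].reset_index(drop=True),
        raw=matrix.raw[keep],
        samples=matrix.samples,
        normalized=None if matrix.normalized is None else matrix.normalized[keep],
        meta={**matrix.meta, "filtered_out": int((~keep).sum())},
    )


def quantile_normalize(matrix: WindowCountMatrix) -> WindowCountMatrix:
    """Full-quantile normalization across sample columns.

    Every column's sorted values are replaced by the across-sample mean of
    order statistics; tied entries within a column receive the average of
    the target values at their tied ranks.
    """
    if matrix.n_samples < 2:
        warnings.warn("quantile normalization needs >= 2 samples; returning input unchanged")
        out = WindowCountMatrix(matrix.windows, matrix.raw, matrix.samples,
                                normalized=matrix.raw.astype(float), meta=dict(matrix.meta))
        return out
    x = matrix.raw.astype(float)
    order = np.argsort(x, axis=0, kind="stable")
    target = np.mean(np.take_along_axis(x, order, axis=0), axis=1)
    normalized = np.empty_like(x)
    n = x.shape[0]
    for j in range(x.shape[1]):
        col = x[:, j]
        o = order[:, j]
        assigned = np.empty(n)
        assigned[o] = target
        # average target values over ties within the column
        sorted_vals = col[o]
        boundaries = np.flatnonzero(np.diff(sorted_vals) != 0) + 1
        groups = np.split(o, boundaries)
        for g in groups:
            if len(g) > 1:
                assigned[g] = assigned[g].mean()
        normalized[:, j] = assigned
    return WindowCountMatrix(matrix.windows, matrix.raw, matrix.samples,
                             normalized=normalized, meta=dict(matrix.meta))


def normalization_offsets(matrix: WindowCountMatrix) -> np.ndarray:
    """Per-sample log scale factors linking raw counts to the normalized scale.

    f_s = sum(raw_s) / sum(normalized_s); the GLM consumes log f_s as an
    offset so dispersion estimation stays on raw counts.
    """
    if matrix.normalized is None:
        raise ValueError("matrix has not been normalized")
    raw_tot = matrix.raw.sum(axis=0).astype(float)
    norm_tot = matrix.normalized.sum(axis=0)
    return np.log(raw_tot / norm_tot)
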