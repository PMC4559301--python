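"""Coefficient-of-variation saturation ("ceiling effect") analysis.

If repeat-dense regions sit near full methylation, the group that loses
methylation gains headroom and hence variability: hypomethylated DMRs
should show a higher CV in Hi than Lo, and hypermethylated DMRs the
reverse.  The CV contrast delta = CV_Hi - CV_Lo per DMR is compared
between the hypo and hyper classes with a Mann-Whitney U test, with a
within-class Wilcoxon signed-rank against zero reported alongside.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._stats import mann_whitney_u, wilcoxon_signed_rank
from .windows import WindowCountMatrix


def window_cv(matrix: WindowCountMatrix, group: str):
    """Per-window CV (sample sd / mean, n-1 denominator) over one group's
    normalized counts.

    Windows with non-positive mean are excluded; returns (cv array with NaN
    at excluded windows, n_excluded).
    """
    if matrix.normalized is None:
        raise ValueError("matrix must be normalized first")
    sel = (matrix.samples["group"] == group).to_numpy()
    if sel.sum() < 2:
        raise ValueError(f"group {group!r} needs >= 2 samples for a CV")
    x = matrix.normalized[:, sel]
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    cv = np.full(len(mean), np.nan)
    ok = mean > 0
    cv[ok] = sd[ok] / mean[ok]
    return cv, int((~ok).sum())


def cv_table(matrix: WindowCountMatrix, dmrs: pd.DataFrame) -> pd.DataFrame:
    """CV records for DMR windows: cv_hi, cv_lo, delta = cv_hi - cv_lo, direction.

    ``dmrs`` must carry chrom/start/end/direction; rows are matched to
    matrix windows by coordinates.
    """
    cv_hi, _ = window_cv(matrix, "Hi")
    cv_lo, _ = window_cv(matrix, "Lo")
    key = matrix.windows.assign(_row=np.arange(matrix.n_windows))
    merged = dmrs.merge(key, on=["chrom", "start", "end"], how="inner")
    rows = merged["_row"].to_numpy()
    out = merged.loc[:, ["chrom", "start", "end", "direction"]].copy()
    out["cv_hi"] = cv_hi[rows]
    out["cv_lo"] = cv_lo[rows]
    out["delta"] = out["cv_hi"] - out["cv_lo"]
    return out.dropna(subset=["delta"]).reset_index(drop=True)


def cv_ceiling_test(records: pd.DataFrame) -> dict:
    """Saturation test report on CV records.

    (a) two-sided Mann-Whitney U of delta between hypo and hyper DMRs;
    (b) per direction class, two-sided Wilcoxon signed-rank of delta
    against zero.  Classes with < 5 records carry a small-sample warning
    flag in the report.
    """
    hypo = records.loc[records["direction"] == "hypo", "delta"].to_numpy()
    hyper = records.loc[records["direction"] == "hyper", "delta"].to_numpy()
    if len(hypo) == 0 or len(hyper) == 0:
        raise ValueError("both direction classes must be non-empty")
    small = {d for d, v in (("hypo", hypo), ("hyper", hyper)) if len(v) < 5}
    if small:
        warnings.warn(f"small direction classes (<5 records): {sorted(small)}")
    u, p = mann_whitney_u(hypo, hyper)
    report = {
        "mann_whitney_u": float(u),
        "mann_whitney_p": float(p),
        "median_delta_hypo": float(np.median(hypo)),
        "median_delta_hyper": float(np.median(hyper)),
        "n_hypo": int(len(hypo)),
        "n_hyper": int(len(hyper)),
        "small_sample_classes": sorted(small),
    }
    for name, v in (("hypo", hypo), ("hyper", hyper)):
        w, wp = wilcoxon_signed_rank(v)
        report[f"wilcoxon_{name}_w"] = float(w)
        report[f"wilcoxon_{name}_p"] = float(wp)
    return report
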