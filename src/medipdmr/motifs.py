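"""Consensus-motif discovery and scanning in DMR-centred sequences.

Discovery is ZOOPS (zero-or-one occurrence per sequence) EM against a
0-order background: each sequence either lacks a site or carries one at a
uniform position on either strand; the E-step computes occurrence
posteriors, the M-step re-estimates the position probability matrix
(pseudocount 0.25) and the occurrence prior.  Scanning scores both strands
with log2 odds and converts scores to exact p-values by dynamic-programming
convolution of the per-column score distributions (discretized to 1000
bins), followed by Benjamini-Hochberg adjustment pooled over all scanned
positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .dmr import bh_adjust

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT_IDX = np.array([3, 2, 1, 0, 4])  # A<->T, C<->G, N->N


@dataclass
class PWM:
    """Position probability matrix (4 x width) with a 0-order background."""

    probabilities: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.25

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probabilities.shape[0] != 4:
            raise ValueError("probabilities must be 4 x width")
        if self.width < 4:
            raise ValueError("motif width must be >= 4")
        col_sums = self.probabilities.sum(axis=0)
        if not np.allclose(col_sums, 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.probabilities.shape[1]

    def log2_odds(self) -> np.ndarray:
        """(5, width) log2(p/bg) with a zero row for N (ratio 1)."""
        lo = np.log2(np.maximum(self.probabilities, 1e-12)
                     / self.background[:, None])
        return np.vstack([lo, np.zeros(self.width)])

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.probabilities.argmax(axis=0))

    def reverse_complement(self) -> "PWM":
        return PWM(self.probabilities[::-1, ::-1].copy(),
                   background=self.background.copy(),
                   pseudocount=self.pseudocount)


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[b] for b in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"unsupported base {exc} in sequence") from exc


def background_model(sequences: Iterable[str]) -> np.ndarray:
    """0-order background frequencies over pooled sequences (pseudocount 1/base)."""
    counts = np.ones(4)
    total_real = 0
    for seq in sequences:
        enc = _encode(seq)
        for b in range(4):
            c = int((enc == b).sum())
            counts[b] += c
            total_real += c
    if total_real == 0:
        raise ValueError("no A/C/G/T bases in input sequences")
    return counts / counts.sum()


def _window_index_matrix(enc: np.ndarray, w: int) -> np.ndarray:
    return np.lib.stride_tricks.sliding_window_view(enc, w)


def _zoops_em_once(windows: List[np.ndarray], w: int, background: np.ndarray,
                   init_pwm: np.ndarray, max_iter: int = 200,
                   tol: float = 1e-6):
    """One EM run; windows[s] stacks both strands' (n_off, w) index rows."""
    log_bg = np.log(np.concatenate([background, [1.0]]))
    pwm = init_pwm.copy()
    lam = 0.5
    llr = -np.inf
    trajectory = []
    for _ in range(max_iter):
        log_ratio = np.vstack([
            np.log(np.maximum(pwm, 1e-12)) - log_bg[:4, None],
            np.zeros((1, w)),
        ])
        counts = np.full((5, w), 0.0)
        counts[:4] += 0.25  # pseudocount
        lam_num = 0.0
        total_llr = 0.0
        ar = np.arange(w)
        for win in windows:
            scores = log_ratio[win, ar].sum(axis=1)
            n_pos = len(scores)
            m = scores.max()
            ratios = np.exp(scores - m)
            site_mass = lam / n_pos * np.exp(m) * ratios.sum()
            denom = (1.0 - lam) + site_mass
            z = (lam / n_pos) * np.exp(scores) / denom
            total_llr += np.log(denom)
            lam_num += site_mass / denom
            for k in ar:
                np.add.at(counts[:, k], win[:, k], z)
        new_pwm = counts[:4] / counts[:4].sum(axis=0, keepdims=True)
        lam = float(np.clip(lam_num / len(windows), 1e-3, 1.0 - 1e-3))
        trajectory.append(total_llr)
        if total_llr - llr < tol * (abs(total_llr) + 1.0) and len(trajectory) > 1:
            pwm = new_pwm
            llr = total_llr
            break
        pwm = new_pwm
        llr = total_llr
    return pwm, lam, llr, trajectory


def discover_motif(sequences: Mapping[str, str] | Sequence[str], width: int,
                   n_restarts: int = 10, seed: int = 0):
    """ZOOPS EM motif discovery; returns (PWM, best log-likelihood ratio, info).

    The returned LLR is the data log-likelihood under the motif model minus
    the background-only log-likelihood; the best of ``n_restarts`` runs is
    kept.  Deterministic given the seed.  ``info`` carries the occurrence
    prior and the per-iteration LLR trajectory of the winning run.
    """
    seqs = list(sequences.values()) if isinstance(sequences, Mapping) else list(sequences)
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    if min(len(s) for s in seqs) < width:
        raise ValueError("motif width exceeds the shortest sequence")
    bg = background_model(seqs)
    rng = np.random.default_rng([int(seed) % (2**31), 23])
    windows = []
    encs = []
    for s in seqs:
        enc = _encode(s)
        encs.append(enc)
        fwd = _window_index_matrix(enc, width)
        rev = _window_index_matrix(_COMPLEMENT_IDX[enc][::-1], width)
        windows.append(np.vstack([fwd, rev]))
    # starting-point search: sample many candidate subsequence seeds, keep
    # the n_restarts whose seed PWM best explains one site per sequence,
    # then run full EM from each (random seeds alone rarely hit a real site)
    n_candidates = max(50 * n_restarts, 500)
    ar = np.arange(width)
    log_bg4 = np.log(bg)
    stacked = np.vstack(windows)
    block_starts = np.concatenate([[0], np.cumsum([len(w) for w in windows])[:-1]])
    seeds = []
    for _ in range(n_candidates):
        si = int(rng.integers(0, len(encs)))
        enc = encs[si]
        off = int(rng.integers(0, len(enc) - width + 1))
        init = np.full((4, width), 0.1)
        for k in range(width):
            b = enc[off + k]
            if b < 4:
                init[b, k] = 0.7
        init /= init.sum(axis=0, keepdims=True)
        lr = np.vstack([np.log(init) - log_bg4[:, None], np.zeros((1, width))])
        scores = lr[stacked, ar].sum(axis=1)
        quick = float(np.maximum.reduceat(scores, block_starts).sum())
        seeds.append((quick, init))
    seeds.sort(key=lambda t: -t[0])
    best = None
    for _, init in seeds[:n_restarts]:
        pwm_mat, lam, llr, traj = _zoops_em_once(windows, width, bg, init)
        if best is None or llr > best[2]:
            best = (pwm_mat, lam, llr, traj)
    # column-shift refinement: EM often locks onto a shifted register of
    # the motif; restarting from shifted copies lets the run with the most
    # informative columns win on likelihood
    improved = True
    while improved:
        improved = False
        for shift in (-3, -2, -1, 1, 2, 3):
            init = np.full((4, width), 0.25)
            if shift > 0:
                init[:, shift:] = best[0][:, : width - shift]
            else:
                init[:, :shift] = best[0][:, -shift:]
            cand = _zoops_em_once(windows, width, bg, init)
            if cand[2] > best[2] + 1e-6:
                best = cand
                improved = True
    pwm_mat, lam, llr, traj = best
    info = {"occurrence_prior": lam, "llr_trajectory": traj}
    return PWM(pwm_mat, background=bg), float(llr), info


def _column_correlation(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _best_alignment_score(q: np.ndarray, t: np.ndarray,
                          min_overlap: int = 4) -> Tuple[int, float]:
    wq, wt = q.shape[1], t.shape[1]
    best = (-10**9, -np.inf)
    for d in range(-(wq - min_overlap), wt - min_overlap + 1):
        qi0, ti0 = max(0, -d), max(0, d)
        n = min(wq - qi0, wt - ti0)
        if n < min_overlap:
            continue
        cors = [_column_correlation(q[:, qi0 + k], t[:, ti0 + k]) for k in range(n)]
        score = float(np.mean(cors))
        if score > best[1]:
            best = (d, score)
    return best


def motif_similarity(query: PWM, target: PWM, n_null: int = 1000,
                     seed: int = 0):
    """Ungapped PWM-PWM similarity (mean column-wise Pearson, both orientations).

    The p-value is empirical against ``n_null`` column-shuffled copies of
    the query, with the add-one rule.  Returns (offset, orientation, score, p).
    """
    if min(query.width, target.width) < 4:
        raise ValueError("overlap constraint (>= 4 columns) unsatisfiable")
    rng = np.random.default_rng([int(seed) % (2**31), 29])
    t_fwd = target.probabilities
    t_rev = target.reverse_complement().probabilities

    def best_over_orientations(qmat):
        d_f, s_f = _best_alignment_score(qmat, t_fwd)
        d_r, s_r = _best_alignment_score(qmat, t_rev)
        if s_f >= s_r:
            return d_f, "+", s_f
        return d_r, "-", s_r

    offset, orient, observed = best_over_orientations(query.probabilities)
    null = np.empty(n_null)
    for i in range(n_null):
        perm = rng.permutation(query.width)
        null[i] = best_over_orientations(query.probabilities[:, perm])[2]
    p = (np.sum(null >= observed - 1e-12) + 1) / (n_null + 1)
    return offset, orient, observed, float(p)


def score_distribution(pwm: PWM, bins: int = 1000):
    """Discretized exact null distribution of the log2-odds score.

    Returns (per-column integer score table (5, w), bin width delta,
    integer offset, survival function over integer scores), where the
    survival function is P(score >= s) for a random background word.
    """
    lo = pwm.log2_odds()[:4]
    col_min = lo.min(axis=0)
    col_max = lo.max(axis=0)
    span = float((col_max - col_min).sum())
    delta = span / bins if span > 0 else 1.0
    q = np.rint((lo - col_min[None, :]) / delta).astype(int)
    max_int = int(q.max(axis=0).sum())
    dist = np.zeros(max_int + 1)
    dist[0] = 1.0
    for k in range(pwm.width):
        new = np.zeros_like(dist)
        for b in range(4):
            new[q[b, k]:] += pwm.background[b] * dist[: len(dist) - q[b, k] or None]
        dist = new
    sf = np.cumsum(dist[::-1])[::-1]
    q_full = np.vstack([q, np.zeros(pwm.width, dtype=int)])  # N contributes 0
    return q_full, delta, col_min.sum(), np.minimum(sf, 1.0)


def scan_sequences(pwm: PWM, sequences: Mapping[str, str],
                   q_thresholds: Sequence[float] = (0.05, 0.1),
                   bins: int = 1000):
    """Scan both strands of every sequence with exact per-position p-values.

    Returns (hits, per_sequence): ``hits`` lists every position at
    q <= max(q_thresholds); ``per_sequence`` carries each sequence's best
    hit (min q) and containment flags per threshold.
    """
    w = pwm.width
    lo = np.vstack([pwm.log2_odds()])
    q_int, delta, base, sf = score_distribution(pwm, bins=bins)
    ar = np.arange(w)
    ids, offs_all, strands_all, scores_all, p_parts = [], [], [], [], []
    for seq_id, seq in sequences.items():
        enc = _encode(seq)
        if len(enc) < w:
            continue
        for strand, e in (("+", enc), ("-", _COMPLEMENT_IDX[enc][::-1])):
            win = _window_index_matrix(e, w)
            scores = lo[win, ar].sum(axis=1)
            ints = q_int[win, ar].sum(axis=1)
            p = sf[np.minimum(ints, len(sf) - 1)]
            offs = (np.arange(len(scores)) if strand == "+"
                    else len(enc) - w - np.arange(len(scores)))
            ids.extend([seq_id] * len(scores))
            offs_all.append(offs)
            strands_all.extend([strand] * len(scores))
            scores_all.append(scores)
            p_parts.append(p)
    if not ids:
        raise ValueError("no sequence long enough to scan")
    hits = pd.DataFrame({
        "seq_id": ids,
        "offset": np.concatenate(offs_all),
        "strand": strands_all,
        "score": np.concatenate(scores_all),
        "p": np.concatenate(p_parts),
    })
    hits["q"] = bh_adjust(np.clip(hits["p"].to_numpy(), np.finfo(float).tiny, 1.0))
    t_max = max(q_thresholds)
    best_idx = hits.groupby("seq_id")["q"].idxmin()
    per_seq = hits.loc[best_idx].set_index("seq_id")
    per_seq = per_seq.rename(columns={"q": "q_min"})
    for t in q_thresholds:
        per_seq[f"contains_q{t}"] = per_seq["q_min"] <= t
    return hits[hits["q"] <= t_max].reset_index(drop=True), per_seq.reset_index()


def motif_enrichment_test(hypo: Tuple[int, int], hyper: Tuple[int, int],
                          expected_hypo_fraction: float) -> dict:
    """Chi-square (1 df) of the hypo/hyper split among motif-containing DMRs.

    ``hypo``/``hyper`` are (containing, total) pairs; the expected split of
    containing DMRs follows ``expected_hypo_fraction`` (e.g. the hypo share
    of all tested DMRs).  Percent containment per direction is reported.
    """
    (c_hypo, n_hypo), (c_hyper, n_hyper) = hypo, hyper
    if n_hypo <= 0 or n_hyper <= 0:
        raise ValueError("totals must be positive")
    n_contain = c_hypo + c_hyper
    report = {
        "pct_hypo_containing": 100.0 * c_hypo / n_hypo,
        "pct_hyper_containing": 100.0 * c_hyper / n_hyper,
        "n_containing": n_contain,
        "chi2": None, "p": None, "skipped": False,
    }
    if n_contain == 0:
        report["skipped"] = True
        return report
    expected = np.array([expected_hypo_fraction, 1.0 - expected_hypo_fraction]) * n_contain
    observed = np.array([c_hypo, c_hyper], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    report["chi2"] = chi2
    report["p"] = float(stats.chi2.sf(chi2, df=1))
    return report
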