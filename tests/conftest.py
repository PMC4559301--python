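"""Shared fixtures: a small simulated study reused across test modules."""

import numpy as np
import pandas as pd
import pytest

import medipdmr as m


@pytest.fixture(scope="session")
def small_config():
    return m.SimConfig(n_chromosomes=2, chrom_length=150_000,
                       n_samples_per_group=6, n_dmr_hypo=12, n_dmr_hyper=8,
                       baseline_depth=50.0, nb_dispersion=0.1, seed=101)


@pytest.fixture(scope="session")
def small_study(small_config):
    genome, annotation, matrix, truth, samples = m.simulate_study(small_config)
    return {"genome": genome, "annotation": annotation, "matrix": matrix,
            "truth": truth, "samples": samples, "config": small_config}


@pytest.fixture(scope="session")
def normalized_small(small_study):
    flt = m.filter_windows(small_study["matrix"])
    return m.quantile_normalize(flt)


@pytest.fixture(scope="session")
def sharp_pwm():
    """A well-determined width-12 motif over a mildly AT-rich background."""
    rng = np.random.default_rng(77)
    probs = np.full((4, 12), 0.05)
    for k, b in enumerate(rng.integers(0, 4, 12)):
        probs[b, k] = 0.85
    return m.PWM(probs, background=np.array([0.3, 0.2, 0.2, 0.3]))


def aligned_column_correlation(found, truth, max_shift=2):
    """Mean column-wise Pearson between two PWMs, maximized over small
    ungapped shifts and both orientations (EM recovers motifs up to shift
    and strand)."""
    def mean_cor(a, b, shift):
        qa = a[:, max(0, shift):]
        qb = b[:, max(0, -shift):]
        n = min(qa.shape[1], qb.shape[1])
        return np.mean([np.corrcoef(qa[:, k], qb[:, k])[0, 1] for k in range(n)])

    best = -1.0
    for mat in (found.probabilities, found.reverse_complement().probabilities):
        for shift in range(-max_shift, max_shift + 1):
            best = max(best, mean_cor(mat, truth.probabilities, shift))
    return best


def toy_samples(n_per_group=4, n_batches=2):
    rows = []
    for g, group in enumerate(["Hi", "Lo"]):
        for i in range(n_per_group):
            # gender blocks, batches cycling: keeps the factors unaliased
            rows.append((f"S{g * n_per_group + i}", group,
                         "F" if i < (n_per_group + 1) // 2 else "M",
                         (i % n_batches) + 1))
    return pd.DataFrame(rows, columns=["sample_id", "group", "gender", "ip_batch"])
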