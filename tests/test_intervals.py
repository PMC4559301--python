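"""Interval spatial statistics: Jaccard, relative distances, permutation nulls,
overlap composition, region-set differences, TFBS progressive enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import medipdmr as m
from medipdmr.core import merge_intervals


def _iv(*rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------- jaccard

def test_jaccard_known_values():
    a = _iv(("chr1", 0, 100))
    assert m.jaccard_measure(a, a.copy()) == pytest.approx(1.0)
    assert m.jaccard_measure(a, _iv(("chr1", 200, 300))) == 0.0
    assert m.jaccard_measure(a, _iv(("chr1", 50, 150))) == pytest.approx(1 / 3)


def test_jaccard_empty_sets_signalled():
    empty = _iv()
    with pytest.raises(ValueError):
        m.jaccard_measure(empty, empty)


def _jaccard_bitmap_oracle(a, b, universe=2000):
    """Independent per-base boolean-array oracle."""
    chroms = set(a["chrom"]) | set(b["chrom"])
    inter = union = 0
    for c in chroms:
        xa = np.zeros(universe, bool)
        xb = np.zeros(universe, bool)
        for _, r in a[a["chrom"] == c].iterrows():
            xa[r["start"]:r["end"]] = True
        for _, r in b[b["chrom"] == c].iterrows():
            xb[r["start"]:r["end"]] = True
        inter += (xa & xb).sum()
        union += (xa | xb).sum()
    return inter / union


def test_jaccard_matches_bitmap_oracle_on_random_sets():
    rng = np.random.default_rng(8)
    for _ in range(25):
        def rand_set(n):
            starts = rng.integers(0, 1900, n)
            lens = rng.integers(1, 100, n)
            chrom = np.where(rng.random(n) < 0.5, "c1", "c2")
            return pd.DataFrame({"chrom": chrom, "start": starts,
                                 "end": np.minimum(starts + lens, 2000)})
        a, b = rand_set(int(rng.integers(1, 50))), rand_set(int(rng.integers(1, 50)))
        assert m.jaccard_measure(a, b) == pytest.approx(_jaccard_bitmap_oracle(a, b))
        assert m.jaccard_measure(b, a) == pytest.approx(m.jaccard_measure(a, b))


def test_jaccard_invariant_to_interval_splitting():
    a = _iv(("chr1", 0, 300))
    a_split = _iv(("chr1", 0, 120), ("chr1", 120, 300))
    b = _iv(("chr1", 100, 400))
    assert m.jaccard_measure(a, b) == pytest.approx(m.jaccard_measure(a_split, b))


# ------------------------------------------------------- relative distance

def test_relative_distance_endpoints():
    ref = _iv(("chr1", 0, 100), ("chr1", 1000, 1100))  # midpoints 50, 1050
    at_mid = _iv(("chr1", 40, 60))                      # midpoint 50
    d, _ = m.relative_distances(at_mid, ref)
    assert d[0] == pytest.approx(0.0)
    halfway = _iv(("chr1", 500, 600))                   # midpoint 550
    d, _ = m.relative_distances(halfway, ref)
    assert d[0] == pytest.approx(0.5)


def test_relative_distance_excludes_outside_range():
    ref = _iv(("chr1", 100, 200), ("chr1", 300, 400))
    q = _iv(("chr1", 0, 20), ("chr1", 500, 600), ("chr1", 200, 260))
    d, excluded = m.relative_distances(q, ref)
    assert excluded == 2 and len(d) == 1


def test_relative_distance_uniform_under_independence():
    rng = np.random.default_rng(9)
    ref_starts = np.sort(rng.choice(100_000, 200, replace=False))
    ref = pd.DataFrame({"chrom": "c", "start": ref_starts, "end": ref_starts + 10})
    q_starts = rng.integers(0, 99_000, 2000)
    q = pd.DataFrame({"chrom": "c", "start": q_starts, "end": q_starts + 10})
    d, _ = m.relative_distances(q, ref)
    assert stats.kstest(d * 2, "uniform").pvalue > 0.01


def test_relative_distance_needs_two_reference_midpoints():
    with pytest.raises(ValueError):
        m.relative_distances(_iv(("chr1", 0, 10)), _iv(("chr1", 0, 10)))


# ------------------------------------------------------------ permutation

def test_self_association_is_maximally_positive():
    rng = np.random.default_rng(10)
    starts = rng.integers(0, 9_000, 40)
    q = pd.DataFrame({"chrom": "c1", "start": starts, "end": starts + 50})
    sa = m.permutation_association(q, q, {"c1": 10_000}, n_perm=199, seed=4)
    assert sa.jaccard_relationship == "positive"
    assert sa.jaccard_p == pytest.approx(2 * 1 / 200)  # two-sided add-one floor


def test_permutation_association_deterministic():
    rng = np.random.default_rng(11)
    starts = rng.integers(0, 9_000, 30)
    q = pd.DataFrame({"chrom": "c1", "start": starts, "end": starts + 50})
    r = pd.DataFrame({"chrom": "c1", "start": starts + 500, "end": starts + 600})
    a = m.permutation_association(q, r, {"c1": 10_000}, n_perm=100, seed=7)
    b = m.permutation_association(q, r, {"c1": 10_000}, n_perm=100, seed=7)
    assert (a.jaccard_p, a.ks_p) == (b.jaccard_p, b.ks_p)


def test_interval_longer_than_chromosome_raises():
    q = _iv(("c1", 0, 20_000))
    with pytest.raises(ValueError):
        m.permutation_association(q, q, {"c1": 10_000}, n_perm=10, seed=1)


def test_queries_inside_sines_show_positive_association(small_study):
    ann = small_study["annotation"]
    genome = small_study["genome"]
    sizes = {c: len(s) for c, s in genome.items()}
    sines = ann.repeats_of_class("SINE")
    q = sines.sample(n=min(60, len(sines)), random_state=0)[
        ["chrom", "start", "end"]].reset_index(drop=True)
    sa = m.permutation_association(q, sines, sizes, n_perm=500, seed=2)
    assert sa.jaccard_relationship == "positive"
    assert sa.jaccard_p < 0.01


# ----------------------------------------------------------- composition

def test_overlap_composition_toy_counts(small_study):
    ann = small_study["annotation"]
    sines = ann.repeats_of_class("SINE").head(10)[["chrom", "start", "end"]]
    comp = m.overlap_composition(sines, ann)
    assert comp["repeat"] == 1.0
    assert comp["repeat_families"]["SINE"] == 1.0


def test_overlap_composition_empty_annotation():
    from medipdmr.simulate import AnnotationSet
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    empty = AnnotationSet(pd.DataFrame(columns=cols), pd.DataFrame(columns=cols),
                          pd.DataFrame(columns=cols))
    comp = m.overlap_composition(_iv(("c1", 0, 300)), empty)
    assert comp["CpGi"] == comp["gene"] == comp["repeat"] == 0.0


def test_overlap_composition_fraction_by_hand():
    from medipdmr.simulate import AnnotationSet
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    genes = pd.DataFrame([("c1", 0, 1000, "g", 0, "+")], columns=cols)
    ann = AnnotationSet(pd.DataFrame(columns=cols), genes,
                        pd.DataFrame(columns=cols))
    dmrs = _iv(*[("c1", 100 + 2000 * i, 400 + 2000 * i) for i in range(10)])
    comp = m.overlap_composition(dmrs, ann)  # only the first DMR overlaps
    assert comp["gene"] == pytest.approx(0.1)


# ------------------------------------------------------------ region sets

def test_region_set_differential_null_and_planted(normalized_small, small_study):
    truth = small_study["truth"]
    planted = truth.planted_dmrs
    hypo = planted[planted["direction"] == "hypo"][["chrom", "start", "end"]]
    hyper = planted[planted["direction"] == "hyper"][["chrom", "start", "end"]]
    rep = m.region_set_differential(normalized_small,
                                    {"hypo": hypo, "hyper": hyper})
    assert rep["per_set_mean_difference"]["hypo"] < 0
    assert rep["per_set_mean_difference"]["hyper"] > 0
    assert rep["p"] < 0.01


def test_region_set_differential_refuses_tiny_sets(normalized_small):
    w = normalized_small.windows.iloc[:1]
    region = _iv((w["chrom"].iloc[0], int(w["start"].iloc[0]),
                  int(w["end"].iloc[0])))
    rep = m.region_set_differential(normalized_small,
                                    {"a": region, "b": region.copy()})
    assert rep["p"] is None


def test_region_set_differential_flags_empty_sets(normalized_small):
    nowhere = _iv(("chrMissing", 0, 300))
    rep = m.region_set_differential(normalized_small, {"a": nowhere})
    assert rep["empty_sets"] == ["a"]


# ---------------------------------------------------------- published DMRs

def test_overlap_with_published_dmrs_identity_and_disjoint():
    dmrs = _iv(("c1", 0, 300), ("c1", 1000, 1300))
    dmrs = dmrs.assign(nearest_gene=["gA", "gB"])
    n_region, n_gene = m.overlap_with_published_dmrs(dmrs, dmrs, ["gA", "gB"])
    assert (n_region, n_gene) == (2, 2)
    far = _iv(("c2", 0, 300))
    n_region, n_gene = m.overlap_with_published_dmrs(dmrs, far, ["gX"])
    assert (n_region, n_gene) == (0, 0)


def test_overlap_with_published_gene_intersection_by_hand():
    dmrs = _iv(*[("c1", i * 1000, i * 1000 + 300) for i in range(10)])
    dmrs = dmrs.assign(nearest_gene=[f"g{i}" for i in range(10)])
    _, n_gene = m.overlap_with_published_dmrs(dmrs, _iv(), ["g1", "g5", "g7"])
    assert n_gene == 3


# ------------------------------------------------------------------ TFBS

def test_tfbs_symmetric_overlaps_give_50_percent():
    rng = np.random.default_rng(12)
    hypo = _iv(*[("c1", s, s + 300) for s in rng.integers(0, 50_000, 300) * 10])
    hyper = _iv(*[("c1", s, s + 300) for s in rng.integers(0, 50_000, 300) * 10])
    whole = _iv(("c1", 0, 600_000))
    out = m.tfbs_progressive_enrichment(hypo, hyper, {"TF": whole})
    assert np.allclose(out["representation_pct"], 50.0)
    assert np.allclose(out["p"], 1.0)


def test_tfbs_hand_chi_square_90_vs_30():
    # 90/300 hypo vs 30/300 hyper overlapping: representation 75 %,
    # chi-square 37.5 on the 2x2, p ~ 9e-10
    hypo = _iv(*[("c1", i * 2000, i * 2000 + 300) for i in range(300)])
    hyper = _iv(*[("c2", i * 2000, i * 2000 + 300) for i in range(300)])
    peaks = pd.concat([hypo.head(90), hyper.head(30)], ignore_index=True)
    out = m.tfbs_progressive_enrichment(hypo, hyper, {"TF": peaks},
                                        window_sizes=(0,))
    row = out.iloc[0]
    assert row["representation_pct"] == pytest.approx(75.0)
    assert row["p"] < 1e-7
    assert row["p"] == pytest.approx(stats.chi2.sf(37.5, 1), rel=1e-6)


def test_tfbs_zero_overlap_reported_as_undefined():
    hypo = _iv(("c1", 0, 300))
    hyper = _iv(("c1", 1000, 1300))
    out = m.tfbs_progressive_enrichment(hypo, hyper,
                                        {"TF": _iv(("c2", 0, 100))},
                                        window_sizes=(0,))
    assert np.isnan(out["representation_pct"].iloc[0])


# ------------------------------------------------- permutation calibration

def test_permutation_p_superuniform_under_independence(small_study):
    genome = small_study["genome"]
    ann = small_study["annotation"]
    sizes = {c: len(s) for c, s in genome.items()}
    sines = ann.repeats_of_class("SINE")
    rng = np.random.default_rng(13)
    ps = []
    for rep in range(40):
        starts = rng.integers(0, 149_000, 50)
        chrom = np.where(rng.random(50) < 0.5, "chr1", "chr2")
        q = pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + 200})
        sa = m.permutation_association(q, sines, sizes, n_perm=99, seed=200 + rep)
        ps.append(sa.jaccard_p)
    assert np.mean(np.array(ps) < 0.05) <= 0.10
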