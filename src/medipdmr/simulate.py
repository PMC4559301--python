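"""Synthetic miniature study generator with known ground truth.

Emulates the statistical structure of a two-group (Hi/Lo hair-cortisol)
MeDIP-seq design: a small multi-chromosome genome with planted repeat
elements (SINE/LINE/LTR/DNAt/snRNA/Low), CpG islands and genes; window
counts that are negative-binomial with CpG-density-dependent means,
IP-batch multipliers and ceiling-saturated methylation levels (repeats
near fully methylated, CpG islands unmethylated); hypomethylation effects
planted preferentially in repeats; motif instances planted in DMR-flanking
sequences; and genotypes independent of group apart from a configurable
confounded subset.

Every generator is a pure function of (inputs, config.seed): the same seed
yields byte-identical FASTA/BED/TSV/VCF output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .core import overlaps_any
from .windows import WindowCountMatrix, tile_windows

BASES = np.array(list("ACGT"))
REPEAT_CLASSES = ("SINE", "LINE", "LTR", "DNAt", "snRNA", "Low")
_REPEAT_LENGTHS = {"SINE": 300, "LINE": 1000, "LTR": 500,
                   "DNAt": 300, "snRNA": 150, "Low": 100}
_CPGI_LENGTH = 600

# methylation saturation levels: repeats near the ceiling, CpG islands
# unmethylated, background intermediate
M_REPEAT = 0.97
M_BACKGROUND = 0.70
M_CPG_ISLAND = 0.05

# ordered ref/alt substitution classes; the four CpG-affecting transitions
# (lose or gain a methylatable CpG) are rarer genome-wide, which is what a
# MeDIP-driven overrepresentation is measured against
SUBSTITUTION_CLASSES = tuple(
    f"{r}/{a}" for r in "ACGT" for a in "ACGT" if r != a
)
CPG_AFFECTING = ("C/T", "G/A", "T/C", "A/G")
BACKGROUND_CLASS_FREQS = {
    cls: (0.05 if cls in CPG_AFFECTING else 0.1) for cls in SUBSTITUTION_CLASSES
}


@dataclass
class SimConfig:
    """Study-design parameters of the simulated experiment."""

    n_chromosomes: int = 2
    chrom_length: int = 600_000
    window_width: int = 300
    n_samples_per_group: int = 24
    n_batches: int = 5
    nb_dispersion: float = 0.1
    baseline_depth: float = 50.0
    n_dmr_hypo: int = 60
    n_dmr_hyper: int = 40
    dmr_log2fc: float = 1.0
    sine_density: float = 0.10
    line_density: float = 0.05
    cpgi_density: float = 0.02
    ltr_density: float = 0.01
    dnat_density: float = 0.01
    snrna_density: float = 0.005
    low_density: float = 0.01
    gene_density: float = 0.20
    bio_sd: float = 0.3
    motif_rate_hypo: float = 0.39
    motif_rate_hyper: float = 0.07
    snp_overrep_factor: float = 3.5
    n_snps: int = 500
    n_confounded_snps: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        dens = {
            "sine_density": self.sine_density, "line_density": self.line_density,
            "cpgi_density": self.cpgi_density, "ltr_density": self.ltr_density,
            "dnat_density": self.dnat_density, "snrna_density": self.snrna_density,
            "low_density": self.low_density, "gene_density": self.gene_density,
        }
        for name, v in dens.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        planted = (self.sine_density + self.line_density + self.cpgi_density
                   + self.ltr_density + self.dnat_density + self.snrna_density
                   + self.low_density)
        if planted > 1.0:
            raise ValueError(f"repeat + CpG-island densities sum to {planted} > 1")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.bio_sd < 0:
            raise ValueError("bio_sd must be >= 0")
        if self.window_width <= 0:
            raise ValueError("window_width must be positive")
        if not 1 <= self.snp_overrep_factor <= 5:
            raise ValueError("snp_overrep_factor must lie in [1, 5] "
                             "(background CpG-class mass 0.2 caps the ratio at 5)")
        for name in ("motif_rate_hypo", "motif_rate_hyper"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} outside [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class AnnotationSet:
    """Planted feature tracks: repeats (class in name), genes, CpG islands."""

    repeats: pd.DataFrame
    genes: pd.DataFrame
    cpg_islands: pd.DataFrame

    def repeats_of_class(self, cls: str) -> pd.DataFrame:
        return self.repeats[self.repeats["name"] == cls].reset_index(drop=True)


@dataclass
class SimTruth:
    """Ground truth of planted effects for recovery testing."""

    planted_dmrs: pd.DataFrame  # chrom, start, end, window_index, direction, log2fc
    m_w: np.ndarray             # per-window saturation level in [0, 1]
    motif_instances: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["seq_id", "offset", "strand"]))
    confounded_snps: tuple = ()


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stream])


def _place_nonoverlapping(rng, occupied: np.ndarray, target_bases: int,
                          length: int) -> list:
    """Greedy uniform placement of fixed-length features avoiding occupied bases."""
    placed = []
    n_needed = int(round(target_bases / length))
    chrom_len = len(occupied)
    attempts = 0
    max_attempts = max(50 * n_needed, 1000)
    while len(placed) < n_needed and attempts < max_attempts:
        attempts += 1
        s = int(rng.integers(0, chrom_len - length + 1))
        if not occupied[s : s + length].any():
            occupied[s : s + length] = True
            placed.append((s, s + length))
    return placed


def generate_genome(config: SimConfig) -> Tuple[Dict[str, str], AnnotationSet]:
    """Random genome with planted repeats, CpG islands and genes.

    Repeats and CpG islands are mutually non-overlapping; genes are placed
    independently (real genes routinely contain repeats).  CpG islands are
    GC-rich stretches, so their CpG-dinucleotide density is several-fold
    the background.
    """
    rng = _rng(config, 1)
    class_density = {
        "SINE": config.sine_density, "LINE": config.line_density,
        "LTR": config.ltr_density, "DNAt": config.dnat_density,
        "snRNA": config.snrna_density, "Low": config.low_density,
    }
    genome: Dict[str, str] = {}
    repeat_rows, cpgi_rows, gene_rows = [], [], []
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        L = config.chrom_length
        occupied = np.zeros(L, dtype=bool)
        for cls in REPEAT_CLASSES:
            target = class_density[cls] * L
            if target <= 0:
                continue
            for s, e in _place_nonoverlapping(rng, occupied, target,
                                              _REPEAT_LENGTHS[cls]):
                repeat_rows.append((chrom, s, e, cls, 0, "."))
        for s, e in _place_nonoverlapping(rng, occupied,
                                          config.cpgi_density * L, _CPGI_LENGTH):
            cpgi_rows.append((chrom, s, e, "CpGi", 0, "."))
        # genes: variable length, non-overlapping with each other only
        gene_occupied = np.zeros(L, dtype=bool)
        gene_target = config.gene_density * L
        placed_bases = 0
        gi = 0
        attempts = 0
        while placed_bases < gene_target and attempts < 10_000:
            attempts += 1
            length = int(rng.integers(2000, 8001))
            s = int(rng.integers(0, L - length + 1))
            if gene_occupied[s : s + length].any():
                continue
            gene_occupied[s : s + length] = True
            strand = "+" if rng.random() < 0.5 else "-"
            gene_rows.append((chrom, s, s + length, f"gene_{chrom}_{gi:04d}", 0, strand))
            gi += 1
            placed_bases += length
        # sequence: AT-rich background, GC-rich CpG islands
        seq = rng.choice(BASES, size=L, p=[0.30, 0.20, 0.20, 0.30])
        for _, s, e, *_ in [r for r in cpgi_rows if r[0] == chrom]:
            seq[s:e] = rng.choice(BASES, size=e - s, p=[0.16, 0.34, 0.34, 0.16])
        genome[chrom] = "".join(seq)
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    annotation = AnnotationSet(
        repeats=pd.DataFrame(repeat_rows, columns=cols),
        genes=pd.DataFrame(gene_rows, columns=cols),
        cpg_islands=pd.DataFrame(cpgi_rows, columns=cols),
    )
    return genome, annotation


def _cpg_per_window(genome: Dict[str, str], windows: pd.DataFrame) -> np.ndarray:
    counts = np.zeros(len(windows), dtype=np.int64)
    for chrom, sub in windows.groupby("chrom", sort=False):
        seq = genome[chrom]
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        is_cg = np.concatenate([(arr[:-1] == ord("C")) & (arr[1:] == ord("G")), [False]])
        pref = np.concatenate([[0], np.cumsum(is_cg)])
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        counts[sub.index] = pref[e - 1] - pref[s]
    return counts


def build_sample_sheet(config: SimConfig) -> pd.DataFrame:
    """Hi/Lo sample sheet with gender, balanced IP batches and cortisol values.

    With the default 24 + 24 design, the gender split mirrors the study
    (Hi: 16 F / 8 M, Lo: 13 F / 11 M); other sizes alternate genders.
    Cortisol is log-normal on either side of the 8.9 fmol/mg threshold.
    """
    rng = _rng(config, 2)
    n = config.n_samples_per_group
    rows = []
    for g, group in enumerate(["Hi", "Lo"]):
        if n == 24:
            genders = ["F"] * (16 if group == "Hi" else 13)
            genders += ["M"] * (n - len(genders))
        else:
            genders = ["F" if i % 2 == 0 else "M" for i in range(n)]
        for i in range(n):
            sid = f"S{g * n + i + 1:02d}"
            batch = (i % config.n_batches) + 1
            spread = abs(rng.normal(0.0, 0.35)) + 0.02
            cort = 8.9 * np.exp(spread if group == "Hi" else -spread)
            rows.append((sid, group, genders[i], batch, round(float(cort), 3)))
    return pd.DataFrame(rows, columns=["sample_id", "group", "gender",
                                       "ip_batch", "hair_cortisol"])


def generate_counts(genome: Dict[str, str], annotation: AnnotationSet,
                    config: SimConfig) -> Tuple[WindowCountMatrix, SimTruth, pd.DataFrame]:
    """Window x sample NB counts with planted differential-methylation effects.

    mean_ws = baseline_depth * depth_s * batch_s * g(CpG_w) * m_eff(w, s)
    with m_eff = clip(m_w * 2^(beta_w * group_s) * eps_ws, 0, 1): effects
    act on the methylation level and saturate at the ceiling.  eps_ws is
    per-individual log-normal(0, bio_sd) biological variability of the
    methylation level; its clipping at the ceiling is what produces the
    saturation ("ceiling") signature the CV analysis detects — near full
    methylation the between-individual variance is compressed, and a group
    that loses methylation regains it.  Set bio_sd = 0 for counts that are
    exactly NB(mean, nb_dispersion).  Hypo DMRs are planted preferentially
    in repeat windows (where m_w = 0.97), hyper DMRs in background windows,
    mirroring hypomethylation targeting retrotransposons.
    """
    rng = _rng(config, 3)
    chrom_sizes = {c: len(s) for c, s in genome.items()}
    windows = tile_windows(chrom_sizes, config.window_width)
    G = len(windows)
    cpg = _cpg_per_window(genome, windows)
    med = max(float(np.median(cpg)), 1.0)
    g_fun = 1.0 + cpg / med
    in_repeat = overlaps_any(windows, annotation.repeats)
    in_cpgi = overlaps_any(windows, annotation.cpg_islands)
    m_w = np.full(G, M_BACKGROUND)
    m_w[in_repeat] = M_REPEAT
    m_w[in_cpgi] = M_CPG_ISLAND  # islands take precedence

    beta = np.zeros(G)
    sine_win = overlaps_any(windows, annotation.repeats_of_class("SINE"))
    # CpG-island windows are near-unmethylated and would not survive the
    # count filter, so they are not eligible DMR hosts
    hypo_pool = np.flatnonzero(sine_win & ~in_cpgi)
    if len(hypo_pool) < config.n_dmr_hypo:
        hypo_pool = np.flatnonzero(in_repeat & ~in_cpgi)
    hyper_pool = np.flatnonzero(~in_repeat & ~in_cpgi)
    if len(hypo_pool) < config.n_dmr_hypo or len(hyper_pool) < config.n_dmr_hyper:
        raise ValueError("not enough eligible windows to plant the requested DMRs")
    hypo_idx = np.sort(rng.choice(hypo_pool, size=config.n_dmr_hypo, replace=False))
    remaining = np.setdiff1d(hyper_pool, hypo_idx)
    hyper_idx = np.sort(rng.choice(remaining, size=config.n_dmr_hyper, replace=False))
    beta[hypo_idx] = -abs(config.dmr_log2fc)
    beta[hyper_idx] = abs(config.dmr_log2fc)

    samples = build_sample_sheet(config)
    n = len(samples)
    is_hi = (samples["group"] == "Hi").to_numpy().astype(float)
    depth_s = np.exp(rng.normal(0.0, 0.1, size=n))
    batch_mult = np.exp(rng.normal(0.0, 0.1, size=config.n_batches))
    b_s = batch_mult[samples["ip_batch"].to_numpy() - 1]

    m_eff = m_w[:, None] * 2.0 ** (beta[:, None] * is_hi[None, :])
    if config.bio_sd > 0:
        m_eff = m_eff * np.exp(rng.normal(0.0, config.bio_sd, size=(G, n)))
    m_eff = np.clip(m_eff, 0.0, 1.0)
    mu = config.baseline_depth * depth_s[None, :] * b_s[None, :] * g_fun[:, None] * m_eff
    phi = config.nb_dispersion
    if phi < 1e-8:
        raw = rng.poisson(mu)
    else:
        r = 1.0 / phi
        p = r / (r + mu)
        raw = rng.negative_binomial(r, p)
    matrix = WindowCountMatrix(windows=windows, raw=raw.astype(np.int64),
                               samples=samples)
    planted = []
    for idx in hypo_idx:
        w = windows.iloc[idx]
        planted.append((w["chrom"], w["start"], w["end"], int(idx), "hypo",
                        -abs(config.dmr_log2fc)))
    for idx in hyper_idx:
        w = windows.iloc[idx]
        planted.append((w["chrom"], w["start"], w["end"], int(idx), "hyper",
                        abs(config.dmr_log2fc)))
    truth = SimTruth(
        planted_dmrs=pd.DataFrame(
            planted, columns=["chrom", "start", "end", "window_index",
                              "direction", "log2fc"]),
        m_w=m_w,
    )
    return matrix, truth, samples


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _sample_motif_instance(rng, pwm) -> str:
    cols = pwm.probabilities.T
    return "".join(BASES[rng.choice(4, p=col / col.sum())] for col in cols)


def generate_sequences_with_motifs(genome: Dict[str, str], truth: SimTruth,
                                   pwm, config: SimConfig,
                                   flank: int = 300) -> Dict[str, str]:
    """DMR-centred sequences (window +/- flank) with planted motif instances.

    A motif drawn from the PWM replaces a uniform-random stretch with
    probability motif_rate_hypo in hypomethylated and motif_rate_hyper in
    hypermethylated DMR sequences; instances (id, offset, strand) are logged
    in ``truth.motif_instances``.
    """
    rng = _rng(config, 4)
    w = pwm.width
    sequences: Dict[str, str] = {}
    instances = []
    for i, row in truth.planted_dmrs.iterrows():
        chrom_seq = genome[row["chrom"]]
        s = max(0, int(row["start"]) - flank)
        e = min(len(chrom_seq), int(row["end"]) + flank)
        seq = chrom_seq[s:e]
        if w > len(seq):
            raise ValueError(f"motif width {w} exceeds sequence length {len(seq)}")
        seq_id = f"dmr{i:04d}_{row['direction']}"
        rate = (config.motif_rate_hypo if row["direction"] == "hypo"
                else config.motif_rate_hyper)
        if rng.random() < rate:
            inst = _sample_motif_instance(rng, pwm)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                inst = inst.translate(_COMPLEMENT)[::-1]
            off = int(rng.integers(0, len(seq) - w + 1))
            seq = seq[:off] + inst + seq[off + w:]
            instances.append((seq_id, off, strand))
        sequences[seq_id] = seq
    truth.motif_instances = pd.DataFrame(instances,
                                         columns=["seq_id", "offset", "strand"])
    return sequences


def generate_genotypes(dmrs: pd.DataFrame, samples: pd.DataFrame,
                       config: SimConfig, span: int = 900):
    """SNPs near DMR midpoints with CpG-affecting classes overrepresented.

    Substitution classes are drawn with the four CpG-affecting transitions
    at ``snp_overrep_factor`` times their background frequency (others
    scaled down to compensate), so the realized observed/background ratio
    equals the factor.  Genotypes are Hardy-Weinberg draws independent of
    group except for ``n_confounded_snps`` SNPs given a strong group-linked
    allele-frequency shift.

    Returns (genotype frame, dosage matrix, truth-updated confounded ids).
    """
    if len(dmrs) == 0:
        raise ValueError("dmrs must be non-empty")
    rng = _rng(config, 5)
    f = config.snp_overrep_factor
    bg = np.array([BACKGROUND_CLASS_FREQS[c] for c in SUBSTITUTION_CLASSES])
    special = np.array([c in CPG_AFFECTING for c in SUBSTITUTION_CLASSES])
    probs = np.where(special, f * bg, 0.0)
    probs[~special] = bg[~special] * (1.0 - probs.sum()) / bg[~special].sum()
    mids = ((dmrs["start"] + dmrs["end"]) // 2).to_numpy()
    chroms = dmrs["chrom"].to_numpy()
    n_hi = int((samples["group"] == "Hi").sum())
    n_lo = len(samples) - n_hi
    is_hi = (samples["group"] == "Hi").to_numpy()
    rows, dosages = [], []
    confounded = [f"snp{j:05d}" for j in
                  rng.choice(config.n_snps, size=config.n_confounded_snps,
                             replace=False)] if config.n_confounded_snps else []
    for j in range(config.n_snps):
        k = int(rng.integers(0, len(dmrs)))
        pos = int(mids[k] + rng.integers(-span // 2, span // 2 + 1))
        cls = SUBSTITUTION_CLASSES[int(rng.choice(len(probs), p=probs))]
        ref, alt = cls.split("/")
        maf = float(rng.uniform(0.05, 0.5))
        sid = f"snp{j:05d}"
        if sid in confounded:
            p_hi = min(maf + 0.35, 0.95)
            p_lo = max(maf - 0.15, 0.02)
            dos = np.where(is_hi, rng.binomial(2, p_hi, size=len(samples)),
                           rng.binomial(2, p_lo, size=len(samples)))
        else:
            dos = rng.binomial(2, maf, size=len(samples))
        rows.append((sid, chroms[k], max(pos, 0), ref, alt, cls))
        dosages.append(dos)
    frame = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "ref", "alt",
                                        "substitution_class"])
    return frame, np.asarray(dosages, dtype=int), tuple(confounded)


def simulate_study(config: SimConfig):
    """Convenience end-to-end generation: genome, annotations, counts, truth."""
    genome, annotation = generate_genome(config)
    matrix, truth, samples = generate_counts(genome, annotation, config)
    return genome, annotation, matrix, truth, samples
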