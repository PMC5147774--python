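"""Synthetic trio-cohort generator.

Produces a fully synthetic study — reference genome, families with correlated
parental ages, truth de novo mutations (with a multi-nucleotide-mutation
cluster process), read-level site observations, replication-timing tracks and
crossover bins — whose statistical structure mirrors a large trio-sequencing
study: ~63 SNVs and ~4.5 indels per proband, a paternal-age effect of
~1.7 SNVs/yr and a maternal effect of ~0.34 SNVs/yr, a mutation-type spectrum
over CpG / non-CpG strong / weak contexts, ~3% of SNVs arising in MNM
clusters, depth-dependent callability and crossover bins of mean length
~201 kb.

The default genome is desk-scale (50 Mb over two chromosomes) rather than
2.68 Gb; mutation *counts* per family are kept at study scale, so per-base
densities are correspondingly higher.  Every stochastic choice flows from a
single seed through ``numpy.random.SeedSequence`` spawning, so a fixed seed
gives a byte-identical cohort.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from scipy.stats import binom

from .core import (
    CONTEXT_CLASSES,
    CONTEXT_CODE,
    KIND_DEL,
    KIND_INS,
    KIND_SNV,
    Family,
    GenomeModel,
    families_to_frame,
    write_pedigree,
)

MEMBERS = ("child", "father", "mother")

# Mutation-type spectrum weights: counts of each (context, change) class in a
# 17812-SNV study cohort; used as sampling weights for generated SNVs.
DEFAULT_SPECTRUM = {
    ("CpG", "transition"): 2984,
    ("CpG", "transversion"): 281,
    ("strong", "transition"): 4264,
    ("strong", "transversion"): 3019,
    ("weak", "transition"): 4758,
    ("weak", "transversion"): 2506,
}

# Intra-cluster consecutive-gap mixture: (weight, lo, hi, scale).  Weights
# chosen so ~19% of gaps are tandem (distance 1), ~57% of clustered mutations
# sit <2 kb from a neighbour and the median gap is ~525 bp.
DEFAULT_MNM_DISTANCE_MIXTURE = (
    (0.19, 1, 1, "uniform"),
    (0.10, 2, 10, "uniform"),
    (0.28, 11, 2000, "log"),
    (0.43, 2001, 20000, "log"),
)

# Transition partners on the collapsed (A/C reference) strand.
TRANSITION = {"A": "G", "C": "T", "G": "A", "T": "C"}
TRANSVERSIONS = {"A": "CT", "C": "AG", "G": "CT", "T": "AG"}


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort.

    Defaults are the study conditions: 283 trios, paternal/maternal SNV-count
    slopes of 1.7 and 0.34 mutations per year of parental age, cohort-mean
    62.9 SNVs and 4.53 indels per proband, deletion:insertion ratio 2.6, and
    parental ages with means 31.6 / 28.9 years and squared correlation 0.65.
    """

    n_families: int = 283
    seed: int = 0

    # genome
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 25_000_000, "chr2": 25_000_000})
    gc_content: float = 0.41
    cpg_obs_exp: float = 0.25      # observed/expected CpG dinucleotide ratio
    n_fraction: float = 0.002      # fraction of genome in N blocks
    n_block_length: int = 5_000

    # families
    father_age_mean: float = 31.6
    mother_age_mean: float = 28.9
    father_age_sd: float = 5.5
    mother_age_sd: float = 5.0
    age_r_squared: float = 0.65
    min_parent_age: float = 15.0

    # mutation counts
    mean_snv_count: float = 62.9
    paternal_slope: float = 1.7
    maternal_slope: float = 0.34
    mean_indel_count: float = 4.53
    indel_paternal_slope: float = 0.1
    indel_maternal_slope: float = 0.01
    deletion_insertion_ratio: float = 2.6
    deletion_length_p: float = 0.47   # geometric; 1 bp deletions commonest
    insertion_length_p: float = 0.72
    max_deletion_length: int = 35
    max_insertion_length: int = 8
    spectrum: dict = field(default_factory=lambda: dict(DEFAULT_SPECTRUM))

    # MNM cluster process
    mnm_fraction: float = 0.031
    mnm_distance_mixture: tuple = DEFAULT_MNM_DISTANCE_MIXTURE
    cluster_size_geometric_p: float = 0.79   # sizes 2.. truncated at 8
    max_cluster_size: int = 8
    tandem_polzeta_fraction: float = 0.20    # tandem pairs forced to GC→AA / GA→TT

    # read-level observations
    depth_mean: float = 35.0
    depth_gamma_shape: float = 25.0          # window-to-window depth dispersion
    base_error_rate: float = 0.005
    window_size: int = 10_000
    background_sites_per_family: int = 200
    population_variant_fraction: float = 0.1  # of background sites
    fs_scale: float = 3.0                     # exponential mean of the FS metric

    # covariate tracks
    n_replication_tracks: int = 5
    track_bin_size: int = 10_000
    track_slope_cap: float = 2.0              # max |Δsignal| between adjacent bins
    crossovers_per_parent: float = 0.65
    crossover_bin_mean_length: float = 201_000.0
    crossover_bin_shape: float = 4.0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if self.paternal_slope < 0 or self.maternal_slope < 0:
            raise ValueError("age slopes must be non-negative")
        if not 0.0 <= self.mnm_fraction <= 1.0:
            raise ValueError("mnm_fraction must lie in [0, 1]")
        if any(w < 0 for w in self.spectrum.values()):
            raise ValueError("spectrum weights must be non-negative")
        if min(self.father_age_mean, self.mother_age_mean,
               self.father_age_sd, self.mother_age_sd) <= 0:
            raise ValueError("age parameters must be positive")

    @property
    def snv_intercept(self) -> float:
        """Intercept making the expected SNV count at mean ages the cohort mean."""
        return self.mean_snv_count - (self.paternal_slope * self.father_age_mean
                                      + self.maternal_slope * self.mother_age_mean)

    @property
    def indel_intercept(self) -> float:
        return self.mean_indel_count - (
            self.indel_paternal_slope * self.father_age_mean
            + self.indel_maternal_slope * self.mother_age_mean)


@dataclass
class CovariateTracks:
    """Replication-timing signals plus per-family crossover bins.

    ``replication`` holds one dict per sequenced individual mapping chromosome
    to a per-bin signal array (high = early replication).  ``crossovers`` is a
    table with columns chrom, start, end (0-based half-open), family_id,
    parent.
    """

    bin_size: int
    replication: list[dict[str, np.ndarray]]
    crossovers: pd.DataFrame


@dataclass
class Cohort:
    """Everything one synthetic study comprises."""

    config: CohortConfig
    genome: GenomeModel
    families: list[Family]
    truth: pd.DataFrame
    observations: pd.DataFrame
    depth_profiles: dict[str, dict[str, np.ndarray]]  # family -> chrom -> (win, 3)
    tracks: CovariateTracks


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def generate_genome(config: CohortConfig,
                    rng: np.random.Generator | None = None) -> GenomeModel:
    """Draw a random genome with the configured GC content and CpG depletion.

    Bases are sampled i.i.d. at a GC fraction pre-compensated (fixed-point)
    for the subsequent CpG thinning step, which breaks a fraction
    ``1 - cpg_obs_exp`` of CpG dinucleotides by replacing their G with A or T.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    total = sum(config.chrom_lengths.values())
    if any(n <= 0 for n in config.chrom_lengths.values()):
        raise ValueError("chromosome lengths must be positive")
    if total < 1000:
        raise ValueError("requested genome is too small (< 1 kb)")

    gc = config.gc_content
    thin = 1.0 - config.cpg_obs_exp
    gc_adj = gc
    for _ in range(8):
        gc_adj = gc + thin * (gc_adj / 2.0) ** 2

    p = np.array([(1 - gc_adj) / 2, gc_adj / 2, gc_adj / 2, (1 - gc_adj) / 2])
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)

    seqs: dict[str, np.ndarray] = {}
    for name, length in config.chrom_lengths.items():
        seq = alphabet[rng.choice(4, size=length, p=p)]
        # thin CpGs: replace the G of a retained-for-breaking CpG with A/T
        cpg_g = np.flatnonzero((seq[:-1] == ord("C")) & (seq[1:] == ord("G"))) + 1
        broken = cpg_g[rng.random(cpg_g.size) < thin]
        seq[broken] = np.where(rng.random(broken.size) < 0.5, ord("A"), ord("T"))
        # N blocks
        n_blocks = int(config.n_fraction * length / config.n_block_length)
        for _ in range(n_blocks):
            start = rng.integers(0, max(1, length - config.n_block_length))
            seq[start:start + config.n_block_length] = ord("N")
        seqs[name] = seq
    return GenomeModel(chrom_names=list(config.chrom_lengths), sequence=seqs)


# ---------------------------------------------------------------------------
# families
# ---------------------------------------------------------------------------

def generate_families(config: CohortConfig,
                      rng: np.random.Generator | None = None) -> list[Family]:
    """Draw trios with bivariate-normal parental ages (r² as configured).

    Ages below ``min_parent_age`` are resampled, which perturbs the moments
    negligibly at the default means (~3 SD above the floor).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_families
    r = float(np.sqrt(config.age_r_squared))
    father = np.empty(n)
    mother = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        z1 = rng.standard_normal(todo.size)
        z2 = rng.standard_normal(todo.size)
        f = config.father_age_mean + config.father_age_sd * z1
        m = config.mother_age_mean + config.mother_age_sd * (
            r * z1 + np.sqrt(1 - r * r) * z2)
        father[todo], mother[todo] = f, m
        todo = todo[(f < config.min_parent_age) | (m < config.min_parent_age)]
    return [
        Family(family_id=f"F{i:04d}", proband_id=f"F{i:04d}_C",
               father_id=f"F{i:04d}_F", mother_id=f"F{i:04d}_M",
               father_age=round(float(father[i]), 2),
               mother_age=round(float(mother[i]), 2))
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# truth mutations
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = ["family_id", "chrom", "pos", "ref_allele", "alt_allele",
                 "kind", "cluster_id", "parent_of_origin"]


def _class_positions(genome: GenomeModel) -> dict[str, np.ndarray]:
    """Concatenated-axis positions (0-based) of each context class."""
    offsets = genome.concat_offsets()
    out = {}
    for cls, code in CONTEXT_CODE.items():
        parts = [np.flatnonzero(genome.context_codes(c) == code) + offsets[c]
                 for c in genome.chrom_names]
        out[cls] = np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)
    return out


def _locate(genome: GenomeModel, concat0: int) -> tuple[str, int]:
    """Concatenated 0-based coordinate -> (chrom, 1-based position)."""
    for c in genome.chrom_names:
        n = genome.sequence[c].size
        if concat0 < n:
            return c, concat0 + 1
        concat0 -= n
    raise ValueError("coordinate beyond genome end")


def _sample_gap(mix, rng: np.random.Generator) -> int:
    weights = np.array([w for w, *_ in mix], dtype=float)
    w, lo, hi, scale = mix[rng.choice(len(mix), p=weights / weights.sum())]
    if lo == hi:
        return int(lo)
    if scale == "log":
        return int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
    return int(rng.integers(lo, hi + 1))


def _snv_alt(ref: str, change: str, rng: np.random.Generator) -> str:
    if change == "transition":
        return TRANSITION[ref]
    return TRANSVERSIONS[ref][rng.integers(2)]


# plus-strand polymerase-ζ tandem signatures: ref dinucleotide -> alt
_POLZETA = {"GC": ("AA", "TT"), "GA": ("TT",), "TC": ("AA",)}


def generate_mutations(genome: GenomeModel, families: list[Family],
                       config: CohortConfig,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Place truth de novo mutations for every family.

    Per-family SNV counts are Poisson around the age-linear mean
    ``intercept + paternal_slope·p + maternal_slope·m``; a fraction
    ``mnm_fraction`` of SNVs is emitted as same-individual MNM clusters whose
    consecutive gaps follow the configured mixture.  Independent SNV positions
    are drawn per context class with the configured spectrum weights; indels
    are placed uniformly with the configured deletion:insertion ratio.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    class_pos = _class_positions(genome)
    for cls in CONTEXT_CLASSES:
        if class_pos[cls].size == 0:
            raise ValueError(f"genome has no {cls} positions; too small/degenerate")

    spec = config.spectrum
    cls_weight = {cls: spec[(cls, "transition")] + spec[(cls, "transversion")]
                  for cls in CONTEXT_CLASSES}
    wsum = sum(cls_weight.values())
    cls_p = np.array([cls_weight[c] / wsum for c in CONTEXT_CLASSES])
    ts_prob = {cls: spec[(cls, "transition")] / cls_weight[cls]
               for cls in CONTEXT_CLASSES}
    offsets = genome.concat_offsets()
    chrom_ends = {c: offsets[c] + genome.sequence[c].size for c in genome.chrom_names}

    p_del = config.deletion_insertion_ratio / (1 + config.deletion_insertion_ratio)
    rows: list[tuple] = []

    def context_of(concat0: int) -> tuple[str, int, str | None]:
        chrom, pos = _locate(genome, concat0)
        code = int(genome.context_codes(chrom)[pos - 1])
        cls = {v: k for k, v in CONTEXT_CODE.items()}.get(code)
        return chrom, pos, cls

    def draw_class_position(cls: str) -> int:
        arr = class_pos[cls]
        return int(arr[rng.integers(arr.size)])

    for fam in families:
        lam = max(0.1, config.snv_intercept
                  + config.paternal_slope * fam.father_age
                  + config.maternal_slope * fam.mother_age)
        n_snv = int(rng.poisson(lam))
        p_pat = (config.paternal_slope * fam.father_age
                 / max(1e-9, config.paternal_slope * fam.father_age
                       + config.maternal_slope * fam.mother_age))

        # split into clustered and independent SNVs
        target_clustered = int(rng.binomial(n_snv, config.mnm_fraction))
        sizes: list[int] = []
        while target_clustered >= 2 and sum(sizes) < target_clustered:
            k = 1 + int(rng.geometric(config.cluster_size_geometric_p))
            sizes.append(min(k, config.max_cluster_size))
        n_clustered = sum(sizes)              # whole clusters kept on overshoot
        n_independent = n_snv - n_clustered

        # independent SNVs, drawn per context class with spectrum weights
        for _ in range(max(0, n_independent)):
            cls = CONTEXT_CLASSES[rng.choice(3, p=cls_p)]
            concat0 = draw_class_position(cls)
            chrom, pos = _locate(genome, concat0)
            ref = genome.base(chrom, pos)
            change = "transition" if rng.random() < ts_prob[cls] else "transversion"
            alt = _snv_alt(ref, change, rng)
            origin = "father" if rng.random() < p_pat else "mother"
            rows.append((fam.family_id, chrom, pos, ref, alt, KIND_SNV, None, origin))

        # MNM clusters
        for j, size in enumerate(sizes):
            gaps = [_sample_gap(config.mnm_distance_mixture, rng)
                    for _ in range(size - 1)]
            polzeta = (size == 2 and gaps[0] == 1
                       and rng.random() < config.tandem_polzeta_fraction)
            placed = None
            for _ in range(200):            # rejection: fit cluster on one chrom
                cls = CONTEXT_CLASSES[rng.choice(3, p=cls_p)]
                anchor = draw_class_position(cls)
                positions = anchor + np.concatenate([[0], np.cumsum(gaps)])
                chrom, _, _ = context_of(anchor)
                if positions[-1] >= chrom_ends[chrom]:
                    continue
                bases = [context_of(int(p0)) for p0 in positions]
                if any(b[2] is None for b in bases):
                    continue
                if polzeta:
                    dinuc = genome.base(bases[0][0], bases[0][1]) + \
                        genome.base(bases[1][0], bases[1][1])
                    if dinuc not in _POLZETA:
                        continue
                placed = bases
                break
            if placed is None:
                continue
            origin = "father" if rng.random() < p_pat else "mother"
            cid = f"{fam.family_id}_c{j}"
            if polzeta:
                alts = _POLZETA[dinuc][rng.integers(len(_POLZETA[dinuc]))]
                for (chrom, pos, _), alt in zip(placed, alts):
                    rows.append((fam.family_id, chrom, pos,
                                 genome.base(chrom, pos), alt, KIND_SNV, cid, origin))
            else:
                for chrom, pos, cls in placed:
                    ref = genome.base(chrom, pos)
                    change = ("transition" if rng.random() < ts_prob[cls]
                              else "transversion")
                    rows.append((fam.family_id, chrom, pos, ref,
                                 _snv_alt(ref, change, rng), KIND_SNV, cid, origin))

        # indels
        lam_i = max(0.05, config.indel_intercept
                    + config.indel_paternal_slope * fam.father_age
                    + config.indel_maternal_slope * fam.mother_age)
        for _ in range(int(rng.poisson(lam_i))):
            is_del = rng.random() < p_del
            if is_del:
                length = min(int(rng.geometric(config.deletion_length_p)),
                             config.max_deletion_length)
            else:
                length = min(int(rng.geometric(config.insertion_length_p)),
                             config.max_insertion_length)
            for _ in range(200):
                chrom = genome.chrom_names[rng.integers(len(genome.chrom_names))]
                seq = genome.sequence[chrom]
                span = length + 1 if is_del else 1
                pos = int(rng.integers(1, seq.size - span))
                window = seq[pos - 1:pos - 1 + span].tobytes().decode()
                if "N" in window:
                    continue
                if is_del:
                    ref, alt = window, window[0]
                    kind = KIND_DEL
                else:
                    ins = "".join("ACGT"[rng.integers(4)] for _ in range(length))
                    ref, alt = window, window + ins
                    kind = KIND_INS
                origin = "father" if rng.random() < p_pat else "mother"
                rows.append((fam.family_id, chrom, pos, ref, alt, kind, None, origin))
                break

    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    truth = truth.drop_duplicates(subset=["family_id", "chrom", "pos"])
    order = {c: i for i, c in enumerate(genome.chrom_names)}
    truth = truth.sort_values(["family_id", "chrom", "pos"],
                              key=lambda s: s.map(order) if s.name == "chrom" else s,
                              kind="mergesort")
    return truth.reset_index(drop=True)


# ---------------------------------------------------------------------------
# read-level observations
# ---------------------------------------------------------------------------

OBS_MEMBER_FIELDS = ["dp", "alt_fwd", "alt_rev", "gl_rr", "gl_ar", "gl_aa"]


def _genotype_log10_likelihoods(alt: np.ndarray, dp: np.ndarray,
                                eps: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """log10 likelihoods of (RR, RA, AA) from alt counts under a binomial model."""
    ln10 = np.log(10.0)
    gl_rr = binom.logpmf(alt, dp, eps) / ln10
    gl_ar = binom.logpmf(alt, dp, 0.5) / ln10
    gl_aa = binom.logpmf(alt, dp, 1 - eps) / ln10
    return gl_rr, gl_ar, gl_aa


def generate_depth_profiles(genome: GenomeModel, families: list[Family],
                            config: CohortConfig,
                            rng: np.random.Generator) -> dict[str, dict[str, np.ndarray]]:
    """Piecewise-constant member depths per window for every family.

    Window depth is Poisson around a Gamma-distributed regional mean, giving
    overdispersed coverage; every site within a window shares its depth.
    """
    shape = config.depth_gamma_shape
    out: dict[str, dict[str, np.ndarray]] = {}
    for fam in families:
        per_chrom = {}
        for chrom in genome.chrom_names:
            n_win = -(-genome.sequence[chrom].size // config.window_size)
            mean = rng.gamma(shape, config.depth_mean / shape, size=(n_win, 3))
            per_chrom[chrom] = rng.poisson(mean).astype(np.int32)
        out[fam.family_id] = per_chrom
    return out


def simulate_observations(truth: pd.DataFrame, families: list[Family],
                          genome: GenomeModel, config: CohortConfig,
                          rng: np.random.Generator | None = None,
                          depth_profiles: dict | None = None,
                          ) -> tuple[pd.DataFrame, dict]:
    """Emit per-site trio observations for truth sites plus background sites.

    True de novo sites carry heterozygous child evidence (alt fraction
    centred at 0.5, split across strands) and error-only parental alt reads;
    background sites are homozygous-reference everywhere, with a configurable
    fraction made inherited population polymorphisms (one parent
    heterozygous, high population likelihood ratio).  Genotype likelihoods
    come from the same binomial read model with ``base_error_rate`` that the
    caller's callability model assumes.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if depth_profiles is None:
        depth_profiles = generate_depth_profiles(genome, families, config, rng)
    eps = config.base_error_rate
    records: list[dict] = []

    alphabet = "ACGT"
    for fam in families:
        fam_truth = truth[truth["family_id"] == fam.family_id]
        sites = [(r.chrom, int(r.pos), r.ref_allele, r.alt_allele, True, False)
                 for r in fam_truth.itertuples()]
        # background (non-mutated) sites
        n_bg = config.background_sites_per_family
        for _ in range(n_bg):
            for _ in range(50):
                chrom = genome.chrom_names[rng.integers(len(genome.chrom_names))]
                pos = int(rng.integers(1, genome.sequence[chrom].size + 1))
                ref = genome.base(chrom, pos)
                if ref != "N":
                    break
            else:
                continue
            alt = alphabet[rng.integers(4)]
            while alt == ref:
                alt = alphabet[rng.integers(4)]
            is_pop = rng.random() < config.population_variant_fraction
            sites.append((chrom, pos, ref, alt, False, is_pop))

        prof = depth_profiles[fam.family_id]
        for chrom, pos, ref, alt, is_dn, is_pop in sites:
            win = (pos - 1) // config.window_size
            dp = prof[chrom][win]           # (3,) child, father, mother
            rec = {"family_id": fam.family_id, "chrom": chrom, "pos": pos,
                   "ref_allele": ref, "alt_allele": alt, "is_denovo": is_dn}
            pop_parent = int(rng.integers(1, 3)) if is_pop else 0
            child_from_pop = is_pop and rng.random() < 0.5
            for i, member in enumerate(MEMBERS):
                d = int(dp[i])
                het = (is_dn and member == "child") or \
                      (is_pop and i == pop_parent) or \
                      (child_from_pop and member == "child")
                k = int(rng.binomial(d, 0.5 if het else eps))
                fwd = int(rng.binomial(k, 0.5))
                rec.update({f"{member}_dp": d,
                            f"{member}_alt_fwd": fwd,
                            f"{member}_alt_rev": k - fwd})
            rec["read_pos_rank_sum"] = float(rng.standard_normal())
            rec["mq_rank_sum"] = float(rng.standard_normal())
            rec["fs"] = float(rng.exponential(config.fs_scale))
            rec["pop_lr"] = 1e6 if is_pop else 0.0
            records.append(rec)

    obs = pd.DataFrame(records)
    for member in MEMBERS:     # genotype likelihoods, vectorised
        d = obs[f"{member}_dp"].to_numpy()
        k = (obs[f"{member}_alt_fwd"] + obs[f"{member}_alt_rev"]).to_numpy()
        gl_rr, gl_ar, gl_aa = _genotype_log10_likelihoods(k, d, eps)
        obs[f"{member}_gl_rr"] = gl_rr
        obs[f"{member}_gl_ar"] = gl_ar
        obs[f"{member}_gl_aa"] = gl_aa
    order = {c: i for i, c in enumerate(genome.chrom_names)}
    obs = obs.sort_values(["family_id", "chrom", "pos"],
                          key=lambda s: s.map(order) if s.name == "chrom" else s,
                          kind="mergesort").reset_index(drop=True)
    return obs, depth_profiles


# ---------------------------------------------------------------------------
# covariate tracks
# ---------------------------------------------------------------------------

def generate_tracks(genome: GenomeModel, families: list[Family],
                    config: CohortConfig,
                    rng: np.random.Generator | None = None) -> CovariateTracks:
    """Smooth replication-timing signals and per-parent crossover bins.

    Each of the ``n_replication_tracks`` individuals shares a smooth cohort
    base signal (sum of long-wavelength sinusoids, range roughly 20–80, high
    = early replication) plus a small smooth individual deviation; adjacent
    bin-to-bin changes are clipped at ``track_slope_cap``.  Crossover counts
    per parent are Poisson and bin lengths Gamma with the configured mean.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    bs = config.track_bin_size

    def smooth_signal(n_bins: int, amp: float, offset: float) -> np.ndarray:
        x = np.arange(n_bins, dtype=float)
        sig = np.zeros(n_bins)
        for wavelength in (500.0, 170.0, 61.0):   # bins; Mb-scale structure
            sig += rng.uniform(0.4, 1.0) * amp * np.sin(
                2 * np.pi * x / wavelength + rng.uniform(0, 2 * np.pi))
        return sig + offset

    base = {c: smooth_signal(-(-genome.sequence[c].size // bs), 14.0, 50.0)
            for c in genome.chrom_names}
    replication = []
    for _ in range(config.n_replication_tracks):
        track = {}
        for c in genome.chrom_names:
            sig = base[c] + smooth_signal(base[c].size, 2.0, 0.0)
            d = np.clip(np.diff(sig), -config.track_slope_cap,
                        config.track_slope_cap)
            track[c] = np.concatenate([[sig[0]], sig[0] + np.cumsum(d)])
        replication.append(track)

    xo_rows = []
    lengths = {c: genome.sequence[c].size for c in genome.chrom_names}
    chroms = genome.chrom_names
    sizes = np.array([lengths[c] for c in chroms], dtype=float)
    for fam in families:
        for parent in ("father", "mother"):
            for _ in range(int(rng.poisson(config.crossovers_per_parent))):
                chrom = chroms[rng.choice(len(chroms), p=sizes / sizes.sum())]
                length = int(rng.gamma(config.crossover_bin_shape,
                                       config.crossover_bin_mean_length
                                       / config.crossover_bin_shape))
                length = max(1000, min(length, lengths[chrom] - 1))
                start = int(rng.integers(0, lengths[chrom] - length))
                xo_rows.append((chrom, start, start + length,
                                fam.family_id, parent))
    crossovers = pd.DataFrame(
        xo_rows, columns=["chrom", "start", "end", "family_id", "parent"])
    return CovariateTracks(bin_size=bs, replication=replication,
                           crossovers=crossovers)


# ---------------------------------------------------------------------------
# orchestration and file output
# ---------------------------------------------------------------------------

def simulate_cohort(config: CohortConfig) -> Cohort:
    """Generate a complete cohort from a single seed."""
    children = np.random.SeedSequence(config.seed).spawn(5)
    rngs = [np.random.default_rng(s) for s in children]
    genome = generate_genome(config, rngs[0])
    families = generate_families(config, rngs[1])
    truth = generate_mutations(genome, families, config, rngs[2])
    obs, depths = simulate_observations(truth, families, genome, config, rngs[3])
    tracks = generate_tracks(genome, families, config, rngs[4])
    return Cohort(config=config, genome=genome, families=families, truth=truth,
                  observations=obs, depth_profiles=depths, tracks=tracks)


def _vcf_header(genome: GenomeModel, fam: Family) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for c in genome.chrom_names:
        header.contigs.add(c, length=genome.sequence[c].size)
    header.add_line('##INFO=<ID=RPRS,Number=1,Type=Float,'
                    'Description="ReadPosRankSum Z-score">')
    header.add_line('##INFO=<ID=MQRS,Number=1,Type=Float,'
                    'Description="MQRankSum Z-score">')
    header.add_line('##INFO=<ID=FS,Number=1,Type=Float,'
                    'Description="Phred-scaled strand bias score">')
    header.add_line('##INFO=<ID=POPLR,Number=1,Type=Float,'
                    'Description="Max population carrier likelihood ratio">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,'
                    'Description="Max-likelihood genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,'
                    'Description="Quality read depth">')
    header.add_line('##FORMAT=<ID=ADF,Number=R,Type=Integer,'
                    'Description="Forward-strand allele depths">')
    header.add_line('##FORMAT=<ID=ADR,Number=R,Type=Integer,'
                    'Description="Reverse-strand allele depths">')
    header.add_line('##FORMAT=<ID=GL,Number=G,Type=Float,'
                    'Description="log10 genotype likelihoods (RR,RA,AA)">')
    for sample in (fam.proband_id, fam.father_id, fam.mother_id):
        header.add_sample(sample)
    return header


def write_family_vcf(obs: pd.DataFrame, fam: Family, genome: GenomeModel,
                     path: str | Path) -> None:
    """Write one family's site observations as an uncompressed VCF 4.2."""
    header = _vcf_header(genome, fam)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        samples = (fam.proband_id, fam.father_id, fam.mother_id)
        for row in obs.itertuples():
            rec = vcf.new_record(contig=row.chrom, start=row.pos - 1,
                                 alleles=(row.ref_allele, row.alt_allele))
            rec.info["RPRS"] = float(row.read_pos_rank_sum)
            rec.info["MQRS"] = float(row.mq_rank_sum)
            rec.info["FS"] = float(row.fs)
            rec.info["POPLR"] = float(row.pop_lr)
            for member, sample in zip(MEMBERS, samples):
                dp = int(getattr(row, f"{member}_dp"))
                af = int(getattr(row, f"{member}_alt_fwd"))
                ar = int(getattr(row, f"{member}_alt_rev"))
                gls = (getattr(row, f"{member}_gl_rr"),
                       getattr(row, f"{member}_gl_ar"),
                       getattr(row, f"{member}_gl_aa"))
                gt = ((0, 0), (0, 1), (1, 1))[int(np.argmax(gls))]
                rec.samples[sample]["GT"] = gt
                rec.samples[sample]["DP"] = dp
                # all reference reads reported on the forward slot; only the
                # alt strand split matters to the filters
                rec.samples[sample]["ADF"] = (dp - af - ar, af)
                rec.samples[sample]["ADR"] = (0, ar)
                rec.samples[sample]["GL"] = (float(getattr(row, f"{member}_gl_rr")),
                                             float(getattr(row, f"{member}_gl_ar")),
                                             float(getattr(row, f"{member}_gl_aa")))
            vcf.write(rec)


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write the whole cohort to disk in plain-text formats.

    Layout: ``genome.fa``, ``pedigree.tsv``, ``truth.tsv``, ``config.json``,
    ``vcf/<family>.vcf``, ``depths/<family>.tsv`` (windowed member depths),
    ``tracks/replication_<i>.bedGraph`` and ``crossovers.bed``.
    """
    out = Path(outdir)
    for sub in ("vcf", "depths", "tracks"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    cohort.genome.to_fasta(out / "genome.fa")
    write_pedigree(cohort.families, out / "pedigree.tsv")
    cohort.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    cfg = dataclasses.asdict(cohort.config)
    cfg["spectrum"] = {f"{k[0]}|{k[1]}": v for k, v in cfg["spectrum"].items()}
    (out / "config.json").write_text(json.dumps(cfg, indent=2, default=str))

    for fam in cohort.families:
        fam_obs = cohort.observations[
            cohort.observations["family_id"] == fam.family_id]
        write_family_vcf(fam_obs, fam, cohort.genome,
                         out / "vcf" / f"{fam.family_id}.vcf")
        rows = []
        prof = cohort.depth_profiles[fam.family_id]
        ws = cohort.config.window_size
        for chrom in cohort.genome.chrom_names:
            arr = prof[chrom]
            for w in range(arr.shape[0]):
                end = min((w + 1) * ws, cohort.genome.sequence[chrom].size)
                rows.append((chrom, w * ws, end, *arr[w]))
        pd.DataFrame(rows, columns=["chrom", "start", "end",
                                    "dp_child", "dp_father", "dp_mother"]
                     ).to_csv(out / "depths" / f"{fam.family_id}.tsv",
                              sep="\t", index=False)

    bs = cohort.tracks.bin_size
    for i, track in enumerate(cohort.tracks.replication):
        with open(out / "tracks" / f"replication_{i}.bedGraph", "w") as fh:
            for chrom, values in track.items():
                length = cohort.genome.sequence[chrom].size
                for w, v in enumerate(values):
                    fh.write(f"{chrom}\t{w * bs}\t{min((w + 1) * bs, length)}"
                             f"\t{v:.3f}\n")
    cohort.tracks.crossovers.to_csv(out / "crossovers.bed", sep="\t",
                                    index=False, header=False)
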