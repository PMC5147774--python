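"""Trio de novo calling filters and probabilistic callability.

A candidate site is accepted as a de novo mutation when seven criteria hold,
evaluated in this fixed order:

1. the proband's genotype likelihood ratio lik(AR)/lik(RR) exceeds 1e10;
2. each parent's lik(RR)/lik(AR) exceeds 200;
3. no outside sequenced individual (descendants of the proband excluded)
   carries the allele with lik(AR)/lik(RR) or lik(AA)/lik(RR) above 1e4;
4. at least 15 quality (base quality >= 20) reads cover the proband and at
   least eight cover each parent;
5. alt-supporting reads make up at least 30% of the proband's quality reads;
6. the alt allele is observed on both strands in the proband;
7. site quality metrics are unremarkable: ReadPosRankSum within [-6, 6],
   MQRankSum above -6 and FS (Phred strand bias) below 20.

Likelihood ratios are compared on the natural scale exactly as stated above
but carried in log10 internally.

Because coverage is uneven, the rate denominator is not a hard callable/
non-callable split but the *callability* C_f(x): the probability that a true
de novo mutation at site x in family f would pass the filters, evaluated
under a binomial read model conditional on the three members' depths (child
alt reads ~ Binomial(d_child, 1/2) split evenly across strands; parental alt
reads ~ Binomial(d_parent, eps)).  Criteria 3 and 7 are depth-independent
and enter as constant pass probabilities (default 1).  The number of callable
sites in a family is the sum of C_f(x) over all surveyed (non-N) positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from scipy.stats import binom

from .core import (
    CONTEXT_CLASSES,
    CONTEXT_CODE,
    Family,
    GenomeModel,
    add_concat_pos,
    annotate_context,
    classify_kind,
    read_pedigree,
)

_LN10 = math.log(10.0)

CRITERION_LABELS = {
    1: "proband_likelihood_ratio",
    2: "parent_likelihood_ratio",
    3: "population_evidence",
    4: "read_depth",
    5: "alt_read_fraction",
    6: "strand_support",
    7: "site_quality_metrics",
}


@dataclass(frozen=True)
class FilterThresholds:
    """Thresholds of the seven calling criteria.

    ``mq_rank_sum_min`` defaults to -6: a symmetric Z-score bound matching
    ReadPosRankSum (the natural reading of the criterion; configurable).
    """

    child_lr_log10: float = 10.0          # lik(AR)/lik(RR) > 1e10
    parent_lr_log10: float = math.log10(200.0)
    population_lr_log10: float = 4.0      # lik ratio > 1e4 disqualifies
    min_child_depth: int = 15
    min_parent_depth: int = 8
    min_alt_fraction: float = 0.30
    read_pos_rank_sum_range: tuple[float, float] = (-6.0, 6.0)
    mq_rank_sum_min: float = -6.0
    fs_max: float = 20.0


DEFAULT_THRESHOLDS = FilterThresholds()


@dataclass
class MemberObservation:
    """One trio member's read summary at a site (quality reads only)."""

    quality_read_count: int
    alt_fwd: int
    alt_rev: int
    gl_rr: float      # log10 genotype likelihoods
    gl_ar: float
    gl_aa: float

    def __post_init__(self) -> None:
        if self.quality_read_count < 0 or self.alt_fwd < 0 or self.alt_rev < 0:
            raise ValueError("read counts must be non-negative")
        if self.alt_fwd + self.alt_rev > self.quality_read_count:
            raise ValueError("alt reads exceed quality read count")
        for gl in (self.gl_rr, self.gl_ar, self.gl_aa):
            if gl is None or not math.isfinite(gl):
                raise ValueError("genotype likelihoods must be finite log10 values")


@dataclass
class SiteObservation:
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    proband: MemberObservation
    father: MemberObservation
    mother: MemberObservation


@dataclass
class SiteMetrics:
    read_pos_rank_sum: float
    mq_rank_sum: float
    fs: float


@dataclass
class PopulationEvidence:
    """Max carrier likelihood ratio over outside individuals, natural scale."""

    max_carrier_lr: float = 0.0


@dataclass(frozen=True)
class FilterDecision:
    accepted: bool
    failed_criterion: int | None = None

    @property
    def failed_label(self) -> str | None:
        return CRITERION_LABELS.get(self.failed_criterion)


def passes_filters(obs: SiteObservation, metrics: SiteMetrics,
                   pop: PopulationEvidence,
                   thresholds: FilterThresholds = DEFAULT_THRESHOLDS,
                   ) -> FilterDecision:
    """Evaluate the seven criteria in order; report the first violation."""
    t = thresholds
    # 1: proband likelihood ratio
    if not obs.proband.gl_ar - obs.proband.gl_rr > t.child_lr_log10:
        return FilterDecision(False, 1)
    # 2: both parents confidently homozygous reference
    for parent in (obs.father, obs.mother):
        if not parent.gl_rr - parent.gl_ar > t.parent_lr_log10:
            return FilterDecision(False, 2)
    # 3: absent from the rest of the sequenced population
    if pop.max_carrier_lr > 10 ** t.population_lr_log10:
        return FilterDecision(False, 3)
    # 4: depth
    if obs.proband.quality_read_count < t.min_child_depth or \
            obs.father.quality_read_count < t.min_parent_depth or \
            obs.mother.quality_read_count < t.min_parent_depth:
        return FilterDecision(False, 4)
    # 5: alt fraction
    alt = obs.proband.alt_fwd + obs.proband.alt_rev
    if alt < t.min_alt_fraction * obs.proband.quality_read_count - 1e-12:
        return FilterDecision(False, 5)
    # 6: both strands
    if obs.proband.alt_fwd < 1 or obs.proband.alt_rev < 1:
        return FilterDecision(False, 6)
    # 7: site quality metrics
    lo, hi = t.read_pos_rank_sum_range
    if not (lo <= metrics.read_pos_rank_sum <= hi
            and metrics.mq_rank_sum > t.mq_rank_sum_min
            and metrics.fs < t.fs_max):
        return FilterDecision(False, 7)
    return FilterDecision(True, None)


# ---------------------------------------------------------------------------
# callability
# ---------------------------------------------------------------------------

@lru_cache(maxsize=200_000)
def _child_pass_prob(depth: int, eps: float, lr_log10: float,
                     min_alt_fraction: float) -> float:
    """P(criteria 1, 5 and 6 pass in the child | true het, depth reads)."""
    if depth == 0:
        return 0.0
    k = np.arange(depth + 1)
    lr = (binom.logpmf(k, depth, 0.5) - binom.logpmf(k, depth, eps)) / _LN10
    ok = (lr > lr_log10) & (k >= min_alt_fraction * depth - 1e-12)
    # both strands seen: alt reads split Binomial(k, 1/2) across strands
    p_both = np.where(k >= 2, 1.0 - 2.0 ** (1.0 - k), 0.0)
    return float(np.sum(binom.pmf(k, depth, 0.5) * ok * p_both))


@lru_cache(maxsize=200_000)
def _parent_pass_prob(depth: int, eps: float, lr_log10: float) -> float:
    """P(criterion 2 passes in one parent | true hom-ref, depth reads)."""
    if depth == 0:
        return 0.0
    j = np.arange(depth + 1)
    lr = (binom.logpmf(j, depth, eps) - binom.logpmf(j, depth, 0.5)) / _LN10
    return float(np.sum(binom.pmf(j, depth, eps) * (lr > lr_log10)))


def site_callability(child_depth: int, father_depth: int, mother_depth: int,
                     error_rate: float = 0.005,
                     thresholds: FilterThresholds = DEFAULT_THRESHOLDS,
                     crit3_pass: float = 1.0, crit7_pass: float = 1.0) -> float:
    """Probability that a true de novo at this site would be called.

    Exact enumeration of the binomial read model over criteria 1, 2, 4, 5
    and 6, conditional on the three members' quality-read depths; criteria 3
    and 7 contribute the constant factors ``crit3_pass`` / ``crit7_pass``.
    """
    if not 0.0 < error_rate < 0.5:
        raise ValueError("error_rate must lie in (0, 0.5)")
    if min(child_depth, father_depth, mother_depth) < 0:
        raise ValueError("depths must be non-negative")
    t = thresholds
    if child_depth < t.min_child_depth or father_depth < t.min_parent_depth \
            or mother_depth < t.min_parent_depth:
        return 0.0
    p = _child_pass_prob(int(child_depth), error_rate, t.child_lr_log10,
                         t.min_alt_fraction)
    p *= _parent_pass_prob(int(father_depth), error_rate, t.parent_lr_log10)
    p *= _parent_pass_prob(int(mother_depth), error_rate, t.parent_lr_log10)
    return p * crit3_pass * crit7_pass


# ---------------------------------------------------------------------------
# cohort-level calling
# ---------------------------------------------------------------------------

OBS_FRAME_MEMBERS = ("child", "father", "mother")


def apply_filters_frame(obs: pd.DataFrame,
                        thresholds: FilterThresholds = DEFAULT_THRESHOLDS,
                        ) -> pd.DataFrame:
    """Vectorised filter evaluation over an observation table.

    Expects the column schema produced by the cohort simulator / VCF reader
    (``child_dp``, ``child_alt_fwd`` ... ``pop_lr``).  Returns the table with
    ``accepted`` and ``failed_criterion`` columns appended.
    """
    t = thresholds
    gl_cols = [f"{m}_gl_{g}" for m in OBS_FRAME_MEMBERS for g in ("rr", "ar", "aa")]
    if obs[gl_cols].isna().any().any():
        raise ValueError("missing genotype likelihoods in observation table")

    fail = np.zeros(len(obs), dtype=np.int8)

    def mark(criterion: int, violated: np.ndarray) -> None:
        newly = violated.to_numpy() & (fail == 0)
        fail[newly] = criterion

    alt = obs["child_alt_fwd"] + obs["child_alt_rev"]
    mark(1, ~(obs["child_gl_ar"] - obs["child_gl_rr"] > t.child_lr_log10))
    mark(2, ~((obs["father_gl_rr"] - obs["father_gl_ar"] > t.parent_lr_log10)
              & (obs["mother_gl_rr"] - obs["mother_gl_ar"] > t.parent_lr_log10)))
    mark(3, obs["pop_lr"] > 10 ** t.population_lr_log10)
    mark(4, (obs["child_dp"] < t.min_child_depth)
            | (obs["father_dp"] < t.min_parent_depth)
            | (obs["mother_dp"] < t.min_parent_depth))
    mark(5, alt < t.min_alt_fraction * obs["child_dp"] - 1e-12)
    mark(6, (obs["child_alt_fwd"] < 1) | (obs["child_alt_rev"] < 1))
    lo, hi = t.read_pos_rank_sum_range
    mark(7, ~((obs["read_pos_rank_sum"] >= lo) & (obs["read_pos_rank_sum"] <= hi)
              & (obs["mq_rank_sum"] > t.mq_rank_sum_min)
              & (obs["fs"] < t.fs_max)))

    out = obs.copy()
    out["accepted"] = fail == 0
    out["failed_criterion"] = np.where(fail == 0, np.nan, fail)
    return out


def read_family_vcf(path: str | Path, fam: Family) -> pd.DataFrame:
    """Read one family VCF into the flat observation schema."""
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = (fam.proband_id, fam.father_id, fam.mother_id)
        for rec in vcf:
            row = {"family_id": fam.family_id, "chrom": rec.chrom,
                   "pos": rec.pos, "ref_allele": rec.ref,
                   "alt_allele": rec.alts[0],
                   "read_pos_rank_sum": float(rec.info["RPRS"]),
                   "mq_rank_sum": float(rec.info["MQRS"]),
                   "fs": float(rec.info["FS"]),
                   "pop_lr": float(rec.info.get("POPLR", 0.0))}
            for member, sample in zip(OBS_FRAME_MEMBERS, samples):
                s = rec.samples[sample]
                gl = s["GL"]
                row.update({f"{member}_dp": int(s["DP"]),
                            f"{member}_alt_fwd": int(s["ADF"][1]),
                            f"{member}_alt_rev": int(s["ADR"][1]),
                            f"{member}_gl_rr": float(gl[0]),
                            f"{member}_gl_ar": float(gl[1]),
                            f"{member}_gl_aa": float(gl[2])})
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class CohortCallability:
    """Window-resolved callability for every family, plus the family sums.

    ``windows`` has one row per genome window (chrom, start, end and per
    context-class position counts); the two matrices hold C_f per family
    (rows) and window (columns) for the SNV and indel models; ``per_family``
    aggregates the callable sums that enter the rate denominators.
    """

    family_ids: list[str]
    windows: pd.DataFrame
    snv_window_callability: np.ndarray
    indel_window_callability: np.ndarray
    per_family: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        n_ctx = self.windows[[f"n_{c}" for c in CONTEXT_CLASSES]].to_numpy()
        ctx_sums = self.snv_window_callability @ n_ctx          # fam x 3
        indel_sums = self.indel_window_callability @ n_ctx.sum(axis=1)
        self.per_family = pd.DataFrame({
            "family_id": self.family_ids,
            "snv_callable_sum": ctx_sums.sum(axis=1),
            "indel_callable_sum": indel_sums,
            **{f"callable_{c}": ctx_sums[:, i]
               for i, c in enumerate(CONTEXT_CLASSES)},
        })

    def mean_window_callability(self) -> np.ndarray:
        """Cohort-mean SNV callability per window (the null-model weights)."""
        return self.snv_window_callability.mean(axis=0)


def genome_window_contexts(genome: GenomeModel, window_size: int) -> pd.DataFrame:
    """Per-window counts of CpG / strong / weak positions."""
    rows = []
    for chrom in genome.chrom_names:
        codes = genome.context_codes(chrom)
        length = codes.size
        for start in range(0, length, window_size):
            chunk = codes[start:start + window_size]
            rows.append((chrom, start, min(start + window_size, length),
                         *(int((chunk == CONTEXT_CODE[c]).sum())
                           for c in CONTEXT_CLASSES)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end",
                                       *(f"n_{c}" for c in CONTEXT_CLASSES)])


def cohort_call_and_callability(
        cohort_dir: str | Path,
        thresholds: FilterThresholds = DEFAULT_THRESHOLDS,
        error_rate: float = 0.005,
        indel_error_rate: float = 0.01,
        crit3_pass: float = 1.0, crit7_pass: float = 1.0,
        ) -> tuple[pd.DataFrame, CohortCallability]:
    """Run calling + callability over a cohort directory.

    The directory must follow the cohort writer's layout (``genome.fa``,
    ``pedigree.tsv``, ``vcf/``, ``depths/``).  Returns the accepted calls
    (annotated with kind, context class and concatenated position) and the
    per-family callability.  Indel callability uses the same enumeration
    with a higher per-read error rate, reflecting that indels are harder to
    call; both are conditional on the same member depths.
    """
    cohort_dir = Path(cohort_dir)
    genome = GenomeModel.from_fasta(cohort_dir / "genome.fa")
    families = read_pedigree(cohort_dir / "pedigree.tsv")

    call_frames = []
    windows = None
    snv_call_rows, indel_call_rows = [], []
    for fam in families:
        obs = read_family_vcf(cohort_dir / "vcf" / f"{fam.family_id}.vcf", fam)
        if len(obs):
            flagged = apply_filters_frame(obs, thresholds)
            acc = flagged[flagged["accepted"]].copy()
            if len(acc):
                acc["individual_id"] = fam.proband_id
                acc["kind"] = [classify_kind(r, a) for r, a in
                               zip(acc["ref_allele"], acc["alt_allele"])]
                call_frames.append(acc[["chrom", "pos", "ref_allele",
                                        "alt_allele", "kind", "family_id",
                                        "individual_id"]])

        depths = pd.read_csv(cohort_dir / "depths" / f"{fam.family_id}.tsv",
                             sep="\t")
        if windows is None:
            ws = int((depths["end"] - depths["start"]).max())
            windows = genome_window_contexts(genome, ws)
        snv_call_rows.append([
            site_callability(dc, df_, dm, error_rate, thresholds,
                             crit3_pass, crit7_pass)
            for dc, df_, dm in zip(depths["dp_child"], depths["dp_father"],
                                   depths["dp_mother"])])
        indel_call_rows.append([
            site_callability(dc, df_, dm, indel_error_rate, thresholds,
                             crit3_pass, crit7_pass)
            for dc, df_, dm in zip(depths["dp_child"], depths["dp_father"],
                                   depths["dp_mother"])])

    callability = CohortCallability(
        family_ids=[f.family_id for f in families],
        windows=windows,
        snv_window_callability=np.asarray(snv_call_rows, dtype=float),
        indel_window_callability=np.asarray(indel_call_rows, dtype=float))

    if call_frames:
        calls = pd.concat(call_frames, ignore_index=True)
        calls = annotate_context(calls, genome)
        calls = add_concat_pos(calls, genome)
    else:
        calls = pd.DataFrame(columns=["chrom", "pos", "ref_allele", "alt_allele",
                                      "kind", "family_id", "individual_id",
                                      "context_class", "concat_pos"])
    return calls, callability
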