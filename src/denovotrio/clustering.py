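"""Multi-nucleotide mutation (MNM) cluster detection and null models.

All distances live on the concatenated-genome axis: chromosomes laid end to
end in karyotype order with no gap, so every mutation has a single integer
coordinate and each simulated replicate yields distance lists of equal
length.  Three forward-scan distance lists are computed from the sorted
mutations: for each mutation, the distance to the next mutation in the list
(any individual), to the next from the same individual, and to the next from
a different individual.

Two null models quantify the expected amount of incidental clustering:

* an *independence simulation* that redraws every individual's mutations
  (per context class, callability-weighted) uniformly at random, summarised
  by per-rank medians over replicates for QQ plots;
* a *label permutation* that keeps the observed positions but reshuffles the
  individual identifiers, summarised by the median clustered fraction.

Clusters are built by single-linkage chaining of same-individual,
same-chromosome mutations with consecutive gaps below a threshold (default
20 kb); a cluster can therefore span more than the threshold.  Tandem events
are pairs at distance exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import KIND_SNV
from .rates import wilson_ci

DEFAULT_MAX_GAP = 20_000


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def nearest_distances(mutations: pd.DataFrame) -> dict[str, np.ndarray]:
    """Forward-scan distances from each mutation to the next one.

    ``mutations`` must be sorted by ``concat_pos``.  Returns the three lists
    keyed ``any`` / ``same_individual`` / ``different_individual``; mutations
    with no eligible successor contribute nothing to a list.
    """
    pos = mutations["concat_pos"].to_numpy(dtype=np.int64)
    if np.any(np.diff(pos) < 0):
        raise ValueError("mutations must be sorted by concat_pos")
    ind = mutations["individual_id"].to_numpy()
    n = pos.size
    out = {"any": pos[1:] - pos[:-1] if n > 1 else np.empty(0, dtype=np.int64)}
    same, diff = [], []
    # forward scan per individual via grouping
    order_by_ind: dict = {}
    for i in range(n):
        order_by_ind.setdefault(ind[i], []).append(i)
    same_next = np.full(n, -1, dtype=np.int64)
    for idxs in order_by_ind.values():
        for a, b in zip(idxs, idxs[1:]):
            same_next[a] = b
    for i in range(n):
        if same_next[i] >= 0:
            same.append(pos[same_next[i]] - pos[i])
    # next from a different individual: backwards sweep keeping the two
    # nearest following indices with distinct individuals
    next_diff = np.full(n, -1, dtype=np.int64)
    last_two: list[int] = []
    for i in range(n - 1, -1, -1):
        for j in last_two:
            if ind[j] != ind[i]:
                next_diff[i] = j
                break
        if last_two and ind[last_two[0]] == ind[i]:
            last_two[0] = i
        else:
            last_two = [i] + last_two[:1]
    for i in range(n):
        if next_diff[i] >= 0:
            diff.append(pos[next_diff[i]] - pos[i])
    out["same_individual"] = np.array(same, dtype=np.int64)
    out["different_individual"] = np.array(diff, dtype=np.int64)
    return out


def _fraction_within(pos: np.ndarray, ind: np.ndarray, threshold: int) -> float:
    """Fraction of mutations with another same-individual mutation strictly
    closer than ``threshold`` (either direction)."""
    order = np.lexsort((pos, ind))
    p, g = pos[order], ind[order]
    same = g[1:] == g[:-1]
    close = (p[1:] - p[:-1] < threshold) & same
    hit = np.zeros(p.size, dtype=bool)
    hit[1:][close] = True
    hit[:-1][close] = True
    return float(hit.mean()) if p.size else 0.0


def observed_fraction_within(mutations: pd.DataFrame, threshold: int) -> float:
    return _fraction_within(mutations["concat_pos"].to_numpy(np.int64),
                            mutations["individual_id"].to_numpy(), threshold)


# ---------------------------------------------------------------------------
# independence simulation null
# ---------------------------------------------------------------------------

@dataclass
class NullDistanceSet:
    """Per-rank medians of the three distance lists over replicates."""

    replicates: int
    rank_medians: dict[str, np.ndarray]
    within_fraction: np.ndarray | None = None  # per replicate, optional


def _draw_positions(counts: np.ndarray, axis_length: int,
                    rng: np.random.Generator,
                    weights_cdf: np.ndarray | None = None,
                    weighted_positions: np.ndarray | None = None) -> np.ndarray:
    total = int(counts.sum())
    if weighted_positions is None:
        return rng.integers(0, axis_length, size=total, dtype=np.int64)
    u = rng.random(total)
    idx = np.searchsorted(weights_cdf, u, side="right")
    return weighted_positions[idx]


def simulate_independence_null(counts_by_class: pd.DataFrame,
                               axis_length: int,
                               replicates: int = 500,
                               seed: int = 0,
                               class_positions: dict[str, np.ndarray] | None = None,
                               class_weights: dict[str, np.ndarray] | None = None,
                               within_threshold: int | None = None,
                               ) -> NullDistanceSet:
    """Simulate mutation sets under independence and summarise distances.

    ``counts_by_class`` has one row per individual and one column per
    context class (an all-in-one ``total`` column is also accepted): each
    replicate gives every individual the same number of mutations per class
    as observed.  Positions are drawn on the concatenated axis; when
    ``class_positions`` (position arrays per class) is given, draws are
    restricted to those positions, optionally weighted by the matching
    ``class_weights`` (e.g. mean callability).  Per-rank medians across
    replicates are returned for QQ plotting; if ``within_threshold`` is set,
    the per-replicate fraction of mutations with a same-individual
    neighbour closer than the threshold is recorded too.
    """
    rng = np.random.default_rng(seed)
    classes = [c for c in counts_by_class.columns]
    counts = counts_by_class.to_numpy(dtype=np.int64)
    n_ind, _ = counts.shape
    per_ind_total = counts.sum(axis=1)
    ind_labels = np.repeat(np.arange(n_ind), per_ind_total)

    cdfs: dict[str, np.ndarray] = {}
    if class_positions is not None:
        for cls, positions in class_positions.items():
            if positions.size == 0 and counts_by_class[cls].sum() > 0:
                raise ValueError(f"class {cls} has mutations but no positions")
            w = (class_weights[cls] if class_weights else
                 np.ones(positions.size))
            if w.sum() <= 0 and counts_by_class[cls].sum() > 0:
                raise ValueError(f"class {cls} has zero total weight")
            cdfs[cls] = np.cumsum(w) / w.sum()

    dist_lists: dict[str, list[np.ndarray]] = {
        "any": [], "same_individual": [], "different_individual": []}
    fractions = np.empty(replicates)
    for rep in range(replicates):
        parts = []
        for j, cls in enumerate(classes):
            if class_positions is None:
                parts.append(_draw_positions(counts[:, j], axis_length, rng))
            else:
                parts.append(_draw_positions(
                    counts[:, j], axis_length, rng,
                    weights_cdf=cdfs[cls],
                    weighted_positions=class_positions[cls]))
        # concatenate class draws in per-individual order
        pos = np.empty(per_ind_total.sum(), dtype=np.int64)
        offsets = np.concatenate([[0], np.cumsum(per_ind_total)])
        cls_offsets = [np.concatenate([[0], np.cumsum(counts[:, j])])
                       for j in range(len(classes))]
        for i in range(n_ind):
            chunks = [parts[j][cls_offsets[j][i]:cls_offsets[j][i + 1]]
                      for j in range(len(classes))]
            pos[offsets[i]:offsets[i + 1]] = np.concatenate(chunks) if chunks \
                else np.empty(0, dtype=np.int64)
        frame = pd.DataFrame({"concat_pos": pos, "individual_id": ind_labels})
        frame = frame.sort_values("concat_pos", kind="mergesort")
        dists = nearest_distances(frame)
        for key in dist_lists:
            dist_lists[key].append(np.sort(dists[key]))
        fractions[rep] = _fraction_within(pos, ind_labels, within_threshold) \
            if within_threshold else np.nan

    medians = {}
    for key, lists in dist_lists.items():
        min_len = min(a.size for a in lists)
        stacked = np.vstack([a[:min_len] for a in lists])
        medians[key] = np.median(stacked, axis=0)
    return NullDistanceSet(replicates=replicates, rank_medians=medians,
                           within_fraction=fractions if within_threshold else None)


def independent_placement_fraction(n_individuals: int,
                                   mean_mutations: float,
                                   axis_length: int,
                                   threshold: int,
                                   replicates: int = 500,
                                   seed: int = 0) -> tuple[float, np.ndarray]:
    """Median clustered fraction when mutations are placed independently.

    Each replicate draws Poisson(``mean_mutations``) positions per individual
    uniformly on the axis and measures the fraction of mutations with a
    same-individual neighbour strictly closer than ``threshold``.  Returns
    (median fraction, per-replicate fractions).
    """
    rng = np.random.default_rng(seed)
    fractions = np.empty(replicates)
    for rep in range(replicates):
        counts = rng.poisson(mean_mutations, size=n_individuals)
        total = int(counts.sum())
        pos = rng.integers(0, axis_length, size=total, dtype=np.int64)
        ind = np.repeat(np.arange(n_individuals), counts)
        fractions[rep] = _fraction_within(pos, ind, threshold)
    return float(np.median(fractions)), fractions


# ---------------------------------------------------------------------------
# label-permutation null
# ---------------------------------------------------------------------------

def permutation_expected_fraction(mutations: pd.DataFrame,
                                  distance_threshold: int = DEFAULT_MAX_GAP,
                                  permutations: int = 500,
                                  seed: int = 0) -> dict:
    """Observed vs label-permuted clustered fraction.

    The observed statistic is the fraction of mutations with another
    same-individual mutation strictly closer than ``distance_threshold``;
    the expectation is the median of the same statistic after permuting the
    individual labels (positions fixed).
    """
    if distance_threshold <= 0:
        raise ValueError("distance threshold must be positive")
    pos = mutations["concat_pos"].to_numpy(np.int64)
    ind = mutations["individual_id"].to_numpy()
    rng = np.random.default_rng(seed)
    observed = _fraction_within(pos, ind, distance_threshold)
    perm = np.empty(permutations)
    for i in range(permutations):
        perm[i] = _fraction_within(pos, rng.permutation(ind),
                                   distance_threshold)
    return {"observed": observed,
            "expected": float(np.median(perm)),
            "permuted": perm,
            "n_mutations": int(pos.size)}


# ---------------------------------------------------------------------------
# cluster construction
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    cluster_id: str
    individual_id: str
    members: pd.DataFrame
    span: int
    n_snv: int
    n_indel: int


def build_clusters(mutations: pd.DataFrame,
                   max_gap: int = DEFAULT_MAX_GAP,
                   include_indels: bool = False,
                   same_chromosome: bool = True) -> list[Cluster]:
    """Single-linkage chaining of same-individual mutations.

    Consecutive same-individual mutations separated by a gap strictly below
    ``max_gap`` are linked; chains of two or more form a cluster (so a
    cluster may span more than ``max_gap`` via short links).  By default
    clusters must lie on one chromosome; ``same_chromosome=False`` reproduces
    pure concatenated-axis behaviour where links may cross chromosome ends.
    """
    muts = mutations if include_indels else mutations[mutations["kind"] == KIND_SNV]
    muts = muts.sort_values("concat_pos", kind="mergesort")
    clusters: list[Cluster] = []
    for ind, group in muts.groupby("individual_id", sort=True):
        pos = group["concat_pos"].to_numpy(np.int64)
        chrom = group["chrom"].to_numpy()
        linked = pos[1:] - pos[:-1] < max_gap
        if same_chromosome:
            linked &= chrom[1:] == chrom[:-1]
        # chain boundaries
        start = 0
        for i in range(pos.size):
            is_last = i == pos.size - 1
            if is_last or not linked[i]:
                if i - start >= 1:      # >= 2 members
                    members = group.iloc[start:i + 1]
                    clusters.append(Cluster(
                        cluster_id=f"{ind}_k{len(clusters)}",
                        individual_id=str(ind),
                        members=members.reset_index(drop=True),
                        span=int(pos[i] - pos[start]),
                        n_snv=int((members["kind"] == KIND_SNV).sum()),
                        n_indel=int((members["kind"] != KIND_SNV).sum())))
                start = i + 1
    return clusters


def cluster_size_histogram(clusters: list[Cluster]) -> pd.Series:
    sizes = pd.Series([len(c.members) for c in clusters], dtype=int)
    return sizes.value_counts().sort_index()


def cluster_truth_rand_index(mutations: pd.DataFrame,
                             clusters: list[Cluster]) -> float:
    """Rand index between inferred cluster membership and a ``cluster_id``
    truth column (singletons count as their own clusters)."""
    key = mutations["family_id"].astype(str) + ":" + \
        mutations["chrom"].astype(str) + ":" + mutations["pos"].astype(str)
    truth_label = {}
    for k, cid, idx in zip(key, mutations.get("cluster_id"), range(len(key))):
        truth_label[k] = cid if isinstance(cid, str) else f"singleton_{idx}"
    pred_label = {k: f"none_{i}" for i, k in enumerate(key)}
    for c in clusters:
        ck = c.members["family_id"].astype(str) + ":" + \
            c.members["chrom"].astype(str) + ":" + c.members["pos"].astype(str)
        for k in ck:
            pred_label[k] = c.cluster_id
    keys = list(key)
    n = len(keys)
    agree = 0
    total = 0
    # O(n^2) over mutations is fine at test scale; restrict pairs to same family
    by_fam: dict[str, list[str]] = {}
    for k, fam in zip(keys, mutations["family_id"].astype(str)):
        by_fam.setdefault(fam, []).append(k)
    for fam_keys in by_fam.values():
        for i in range(len(fam_keys)):
            for j in range(i + 1, len(fam_keys)):
                a, b = fam_keys[i], fam_keys[j]
                same_truth = truth_label[a] == truth_label[b]
                same_pred = pred_label[a] == pred_label[b]
                agree += same_truth == same_pred
                total += 1
    return agree / total if total else 1.0


# ---------------------------------------------------------------------------
# tandem events
# ---------------------------------------------------------------------------

@dataclass
class TandemSummary:
    n_adjoining_mutations: int
    n_events: int
    n_snv_total: int
    rate: float
    ci_low: float
    ci_high: float
    events: list[pd.DataFrame]
    adjoining_over_clustered: float | None = None


def tandem_events(mutations: pd.DataFrame,
                  clustered_count: int | None = None) -> TandemSummary:
    """Collapse immediately adjoining same-individual SNV pairs into events.

    Runs of three or more mutually adjacent SNVs count as a single
    multi-base event; the pairs-to-events halving applies only to isolated
    pairs.  The tandem rate is events / total SNVs, with a Wilson interval.
    """
    snvs = mutations[mutations["kind"] == KIND_SNV].sort_values(
        "concat_pos", kind="mergesort")
    events: list[pd.DataFrame] = []
    n_adjoining = 0
    for _, group in snvs.groupby("individual_id", sort=True):
        pos = group["concat_pos"].to_numpy(np.int64)
        adjacent = pos[1:] - pos[:-1] == 1
        start = 0
        for i in range(pos.size):
            if i == pos.size - 1 or not adjacent[i]:
                if i - start >= 1:
                    events.append(group.iloc[start:i + 1].reset_index(drop=True))
                    n_adjoining += i - start + 1
                start = i + 1
    n_total = len(snvs)
    rate = len(events) / n_total if n_total else 0.0
    low, high = wilson_ci(len(events), n_total) if n_total else (0.0, 0.0)
    return TandemSummary(
        n_adjoining_mutations=n_adjoining, n_events=len(events),
        n_snv_total=n_total, rate=rate, ci_low=low, ci_high=high,
        events=events,
        adjoining_over_clustered=(n_adjoining / clustered_count
                                  if clustered_count else None))


# ---------------------------------------------------------------------------
# subsampling comparison
# ---------------------------------------------------------------------------

def subsample_cluster_fraction(mutations: pd.DataFrame,
                               target_mean_per_individual: float,
                               distance_threshold: int = DEFAULT_MAX_GAP,
                               replicates: int = 200,
                               seed: int = 0) -> dict:
    """Clustered fraction after thinning to a target per-individual mean.

    Each mutation is kept with probability target/observed mean (Bernoulli
    thinning); the clustered fraction is recomputed per replicate.  Returns
    the mean fraction and a 2.5–97.5 percentile interval over replicates.
    """
    snvs = mutations[mutations["kind"] == KIND_SNV]
    observed_mean = len(snvs) / snvs["individual_id"].nunique()
    if target_mean_per_individual > observed_mean:
        raise ValueError("target mean exceeds the observed per-individual mean")
    keep_p = target_mean_per_individual / observed_mean
    pos = snvs["concat_pos"].to_numpy(np.int64)
    ind = snvs["individual_id"].to_numpy()
    rng = np.random.default_rng(seed)
    fracs = np.empty(replicates)
    for i in range(replicates):
        keep = rng.random(pos.size) < keep_p
        fracs[i] = _fraction_within(pos[keep], ind[keep], distance_threshold)
    return {"keep_probability": keep_p,
            "mean_fraction": float(fracs.mean()),
            "ci_low": float(np.percentile(fracs, 2.5)),
            "ci_high": float(np.percentile(fracs, 97.5)),
            "fractions": fracs}


# ---------------------------------------------------------------------------
# read-backed phasing
# ---------------------------------------------------------------------------

PHASE_SAME = "same-chromosome"
PHASE_DIFFERENT = "different-chromosome"
PHASE_INCONSISTENT = "inconsistent"
PHASE_NO_CALL = "no-call"


def phase_by_reads(read_observations: pd.DataFrame,
                   min_concordance: float = 0.90) -> pd.DataFrame:
    """Phase pairs of clustered mutations from read-level allele calls.

    ``read_observations`` has one row per (read, site): columns ``read_id``,
    ``pos`` and ``is_alt``.  For every pair of positions covered by common
    reads, reads with matching allele states (alt-alt or ref-ref) support a
    cis configuration; if at least ``min_concordance`` of informative reads
    agree on one configuration that phasing is called, otherwise the pair is
    inconsistent.  Pairs with no informative reads are no-calls.
    """
    verdicts = []
    positions = sorted(read_observations["pos"].unique())
    by_read: dict = {}
    for row in read_observations.itertuples():
        by_read.setdefault(row.read_id, {})[row.pos] = bool(row.is_alt)
    for i in range(len(positions)):
        for j in range(i + 1, len(positions)):
            a, b = positions[i], positions[j]
            cis = trans = 0
            for alleles in by_read.values():
                if a in alleles and b in alleles:
                    if alleles[a] == alleles[b]:
                        cis += 1
                    else:
                        trans += 1
            total = cis + trans
            if total == 0:
                verdict = PHASE_NO_CALL
            elif cis / total >= min_concordance:
                verdict = PHASE_SAME
            elif trans / total >= min_concordance:
                verdict = PHASE_DIFFERENT
            else:
                verdict = PHASE_INCONSISTENT
            verdicts.append((a, b, cis, trans, verdict))
    return pd.DataFrame(verdicts, columns=["pos_a", "pos_b", "cis_reads",
                                           "trans_reads", "verdict"])
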