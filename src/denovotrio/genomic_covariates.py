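"""Replication-timing and recombination covariate tests.

Replication timing enters as the positionwise mean of several individuals'
wavelet-smoothed signals (high = early replication, low = late).  Three
analyses quantify its association with the mutation rate, each stratified by
sequence context (CpG / non-CpG strong / weak) to avoid composition
confounding:

* per-decile PPPY rates over the callability-weighted signal distribution;
* a weighted logistic regression of mutated-vs-callable on signal value with
  context indicators;
* a Cochran–Mantel–Haenszel combined odds ratio of a late/early median
  split, computed separately for clustered and non-clustered mutations
  (OR > 1 means excess mutations in the late-replicating half).

Recombination is tested by counting de novo calls inside their own family's
crossover bins and permuting whole bin lists across families (5000 rounds,
add-one p-value, median permuted count as the expectation).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .core import CONTEXT_CLASSES, Family
from .rates import wilson_ci


# ---------------------------------------------------------------------------
# replication tracks
# ---------------------------------------------------------------------------

@dataclass
class ReplicationTrack:
    """A piecewise-constant genome signal (bedGraph-backed).

    ``intervals`` maps chromosome to (starts, ends, values) arrays with
    0-based half-open coordinates; positions not covered by any interval
    have no data (NaN).
    """

    intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]

    @classmethod
    def from_bedgraph(cls, path: str | Path) -> "ReplicationTrack":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "value"],
                         dtype={"chrom": str})
        out = {}
        for chrom, g in df.groupby("chrom", sort=False):
            g = g.sort_values("start")
            out[chrom] = (g["start"].to_numpy(np.int64),
                          g["end"].to_numpy(np.int64),
                          g["value"].to_numpy(float))
        return cls(intervals=out)

    def values_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Signal at 1-based positions (NaN outside covered intervals)."""
        out = np.full(len(positions), np.nan)
        if chrom not in self.intervals:
            return out
        starts, ends, values = self.intervals[chrom]
        pos0 = np.asarray(positions, dtype=np.int64) - 1
        idx = np.searchsorted(starts, pos0, side="right") - 1
        ok = (idx >= 0) & (pos0 < ends[np.clip(idx, 0, len(ends) - 1)])
        out[ok] = values[idx[ok]]
        return out


def average_tracks(tracks: list[ReplicationTrack],
                   require_all: bool = False) -> ReplicationTrack:
    """Positionwise mean signal across tracks.

    Positions missing from every track stay NaN; with ``require_all`` a
    position missing from *any* track is dropped instead.  Tracks are
    expected on a common interval grid (as written by the cohort
    generator); the mean is taken interval-by-interval.
    """
    if not tracks:
        raise ValueError("need at least one replication track")
    first = tracks[0]
    out: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, (starts, ends, _) in first.intervals.items():
        stack = []
        for t in tracks:
            s, e, v = t.intervals[chrom]
            if s.size != starts.size or not np.array_equal(s, starts):
                raise ValueError("tracks are not on a common interval grid")
            stack.append(v)
        arr = np.vstack(stack)
        have = (~np.isnan(arr)).sum(axis=0)
        total = np.nansum(arr, axis=0)
        mean = np.where(have > 0, total / np.maximum(have, 1), np.nan)
        if require_all:
            mean = np.where(have < arr.shape[0], np.nan, mean)
        out[chrom] = (starts, ends, mean)
    return ReplicationTrack(intervals=out)


# ---------------------------------------------------------------------------
# signal / callability aggregation
# ---------------------------------------------------------------------------

def aggregate_by_signal(calls: pd.DataFrame, callability_windows: pd.DataFrame,
                        mean_window_callability: np.ndarray,
                        track: ReplicationTrack,
                        person_years: float,
                        decimals: int = 2) -> pd.DataFrame:
    """Aggregate mutated counts and callable mass per (signal value, context).

    ``callability_windows`` is the window table from the calling stage
    (chrom/start/end plus per-context position counts) and
    ``mean_window_callability`` the cohort-mean callability per window; the
    signal is evaluated at window midpoints (the generator writes tracks on
    the same grid) and rounded to ``decimals`` to bound the design size.
    ``person_years`` scales the callable mass into the PPPY denominator
    Σ_f (p_f+m_f)·C_f under the cohort-mean approximation.
    """
    win = callability_windows
    mids = ((win["start"] + win["end"]) // 2 + 1).to_numpy()
    signal = np.concatenate([
        track.values_at(chrom, mids[(win["chrom"] == chrom).to_numpy()])
        for chrom in win["chrom"].unique()
    ]) if len(win) else np.empty(0)
    # rebuild in original row order (groupby above keeps order of appearance)
    signal_full = np.full(len(win), np.nan)
    start_idx = 0
    for chrom in win["chrom"].unique():
        mask = (win["chrom"] == chrom).to_numpy()
        signal_full[mask] = signal[start_idx:start_idx + mask.sum()]
        start_idx += mask.sum()
    win = win.assign(signal=np.round(signal_full, decimals),
                     callability=mean_window_callability)
    win = win[np.isfinite(win["signal"])]

    call_signal = np.full(len(calls), np.nan)
    for chrom in calls["chrom"].unique():
        m = (calls["chrom"] == chrom).to_numpy()
        call_signal[m] = track.values_at(
            chrom, calls.loc[m, "pos"].to_numpy(np.int64))
    calls = calls.assign(signal=np.round(call_signal, decimals))
    calls = calls[np.isfinite(calls["signal"])]

    rows = []
    for ctx in CONTEXT_CLASSES:
        mut = calls[calls["context_class"] == ctx] \
            .groupby("signal").size()
        mass = (win[f"n_{ctx}"] * win["callability"]).groupby(
            win["signal"]).sum() * person_years
        for value in mass.index.union(mut.index):
            rows.append((ctx, float(value),
                         int(mut.get(value, 0)),
                         float(mass.get(value, 0.0))))
    return pd.DataFrame(rows, columns=["context_class", "signal",
                                       "mutated", "callable_mass"])


def replication_decile_rates(aggregated: pd.DataFrame) -> pd.DataFrame:
    """Split the callable genome into signal deciles; per-decile PPPY rates.

    Decile boundaries come from the callability-weighted signal
    distribution, so each decile carries ~10% of the callable mass; rates
    are reported per context class with Wilson intervals.
    """
    agg = aggregated.sort_values("signal")
    total_mass = agg.groupby("signal")["callable_mass"].sum()
    if total_mass.index.size < 2:
        raise ValueError("signal is degenerate; deciles undefined")
    cum = total_mass.cumsum() / total_mass.sum()
    # decile of each distinct signal value
    decile_of = pd.Series(np.minimum((cum * 10).apply(np.ceil).astype(int),
                                     10), index=total_mass.index)
    agg = agg.assign(decile=agg["signal"].map(decile_of))
    rows = []
    for (decile, ctx), g in agg.groupby(["decile", "context_class"]):
        n = int(g["mutated"].sum())
        mass = float(g["callable_mass"].sum())
        mean_sig = float((g["signal"] * g["callable_mass"]).sum()
                         / mass) if mass else np.nan
        if mass > 0:
            low, high = wilson_ci(n, mass)
            rows.append((decile, ctx, mean_sig, n, mass, n / mass, low, high))
    return pd.DataFrame(rows, columns=["decile", "context_class",
                                       "mean_signal", "mutated",
                                       "callable_mass", "rate_pppy",
                                       "ci_low", "ci_high"])


def replication_association_test(aggregated: pd.DataFrame) -> dict:
    """Weighted logistic regression of mutated-vs-callable on the signal.

    Uses the per-(signal value, context) aggregation: response is the
    mutated fraction with the callable mass as weights, covariates are the
    signal value and context-class indicators.  A negative slope means more
    mutations at low (late-replicating) signal values.  Perfect-separation
    fits are reported, not silently dropped.
    """
    agg = aggregated[aggregated["callable_mass"] > 0].copy()
    trials = agg["mutated"] + agg["callable_mass"]
    y = agg["mutated"] / trials
    ctx_dummies = pd.get_dummies(agg["context_class"], drop_first=True,
                                 dtype=float)
    X = sm.add_constant(pd.concat([agg["signal"].rename("signal"),
                                   ctx_dummies], axis=1)).astype(float)
    try:
        fit = sm.GLM(y, X, family=sm.families.Binomial(),
                     var_weights=trials).fit()
    except Exception as exc:       # separation and similar degeneracies
        return {"slope": np.nan, "se": np.nan, "p_value": np.nan,
                "error": str(exc)}
    return {"slope": float(fit.params["signal"]),
            "se": float(fit.bse["signal"]),
            "p_value": float(fit.pvalues["signal"]),
            "converged": bool(fit.converged)}


# ---------------------------------------------------------------------------
# Cochran-Mantel-Haenszel combined odds ratio
# ---------------------------------------------------------------------------

@dataclass
class CMHResult:
    """Combined odds ratio of 2x2 strata (late/early x mutated/callable)."""

    tables: list[np.ndarray]
    odds_ratio: float
    ci_low: float
    ci_high: float


def cmh_odds_ratio(tables: list[np.ndarray], level: float = 0.95) -> CMHResult:
    """Mantel-Haenszel pooled OR with the Robins-Breslow-Greenland interval.

    Each table is [[a, b], [c, d]] with rows = (mutated, non-mutated
    callable) and columns = (late, early).  Strata with an empty margin drop
    out of the sums naturally (their terms are zero).
    """
    tabs = [np.asarray(t, dtype=float) for t in tables]
    if not tabs:
        raise ValueError("need at least one stratum")
    num = sum(t[0, 0] * t[1, 1] / t.sum() for t in tabs if t.sum() > 0)
    den = sum(t[0, 1] * t[1, 0] / t.sum() for t in tabs if t.sum() > 0)
    if num <= 0 or den <= 0:
        raise ValueError("pooled odds ratio undefined (zero margin overall)")
    or_mh = num / den
    # Robins-Breslow-Greenland variance of log(OR_MH)
    s1 = s2 = s3 = 0.0
    for t in tabs:
        n = t.sum()
        if n == 0:
            continue
        p = (t[0, 0] + t[1, 1]) / n
        q = (t[0, 1] + t[1, 0]) / n
        r = t[0, 0] * t[1, 1] / n
        s = t[0, 1] * t[1, 0] / n
        s1 += p * r
        s2 += p * s + q * r
        s3 += q * s
    var = s1 / (2 * num ** 2) + s2 / (2 * num * den) + s3 / (2 * den ** 2)
    z = norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return CMHResult(tables=tabs, odds_ratio=float(or_mh),
                     ci_low=float(or_mh * np.exp(-half)),
                     ci_high=float(or_mh * np.exp(half)))


def clustered_cmh_or(aggregated_by_group: dict[str, pd.DataFrame]) -> dict:
    """Late/early CMH odds ratio per clustering group.

    ``aggregated_by_group`` maps a group label (e.g. a clustering-distance
    stratum or "non-clustered") to its (signal, context) aggregation.  The
    late/early split point is the callability-weighted median signal of the
    pooled aggregation; within each group, one 2x2 table per context class
    (mutated/callable x late/early) feeds the combined OR.  OR > 1 means
    excess mutations in the late half.
    """
    pooled = pd.concat(aggregated_by_group.values())
    mass = pooled.groupby("signal")["callable_mass"].sum().sort_index()
    cum = mass.cumsum() / mass.sum()
    median_signal = float(mass.index[np.searchsorted(cum.to_numpy(), 0.5)])

    results = {}
    for group, agg in aggregated_by_group.items():
        tables = []
        for ctx in CONTEXT_CLASSES:
            sub = agg[agg["context_class"] == ctx]
            late = sub["signal"] <= median_signal   # low signal = late
            a = float(sub.loc[late, "mutated"].sum())
            b = float(sub.loc[~late, "mutated"].sum())
            c = float(sub.loc[late, "callable_mass"].sum())
            d = float(sub.loc[~late, "callable_mass"].sum())
            tables.append(np.array([[a, b], [c, d]]))
        results[group] = cmh_odds_ratio(tables)
    return {"median_signal": median_signal, "results": results}


# ---------------------------------------------------------------------------
# crossover overlap permutation test
# ---------------------------------------------------------------------------

def read_crossover_bed(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom", "start", "end", "family_id", "parent"],
                       dtype={"chrom": str, "family_id": str})


def _in_bins_count(pos_by_chrom: dict[str, np.ndarray],
                   bins: pd.DataFrame) -> int:
    """Calls (1-based positions per chromosome) inside half-open [start, end)
    0-based bins: a call at p overlaps iff start < p <= end."""
    total = 0
    for chrom, group in bins.groupby("chrom"):
        pos = pos_by_chrom.get(chrom)
        if pos is None or not len(group):
            continue
        starts = group["start"].to_numpy(np.int64)
        ends = group["end"].to_numpy(np.int64)
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        idx = np.searchsorted(starts, pos, side="right") - 1
        safe = np.clip(idx, 0, len(ends) - 1)
        ok = (idx >= 0) & (pos <= ends[safe]) & (pos > starts[safe])
        total += int(ok.sum())
    return total


def crossover_overlap_test(calls: pd.DataFrame, crossover_bins: pd.DataFrame,
                           permutations: int = 5000, seed: int = 0,
                           strict_greater: bool = False) -> dict:
    """Permutation test of de novo calls overlapping own-family crossover bins.

    Only families with mapped crossover bins take part.  The observed
    statistic counts calls inside a bin of their own family (either
    parent); each permutation reassigns whole bin lists to families
    uniformly at random (a permutation of the family labels), and the
    add-one p-value counts permuted counts >= observed (or > observed with
    ``strict_greater``).  The expected count is the permuted median.

    All family-by-binlist overlap counts are precomputed once, so each
    permutation reduces to an index lookup.
    """
    fams = sorted(set(crossover_bins["family_id"]) & set(calls["family_id"]))
    if len(fams) < 2:
        raise ValueError("need at least two families with crossover bins")
    pos_by_family = {
        f: {chrom: np.sort(g["pos"].to_numpy(np.int64))
            for chrom, g in calls[calls["family_id"] == f].groupby("chrom")}
        for f in fams}
    bins_by_family = {f: crossover_bins[crossover_bins["family_id"] == f]
                      for f in fams}
    n = len(fams)
    pair_counts = np.empty((n, n), dtype=np.int64)
    for i, fc in enumerate(fams):
        for j, fb in enumerate(fams):
            pair_counts[i, j] = _in_bins_count(pos_by_family[fc],
                                               bins_by_family[fb])
    observed = int(pair_counts.diagonal().sum())

    rng = np.random.default_rng(seed)
    rows = np.arange(n)
    perm_counts = np.empty(permutations, dtype=np.int64)
    for i in range(permutations):
        perm_counts[i] = pair_counts[rows, rng.permutation(n)].sum()
    exceed = (perm_counts > observed if strict_greater
              else perm_counts >= observed)
    expected = float(np.median(perm_counts))
    return {"observed": observed,
            "expected": expected,
            "excess": observed / expected - 1 if expected else np.inf,
            "p_value": (1 + int(exceed.sum())) / (1 + permutations),
            "n_families": len(fams),
            "permuted": perm_counts}
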