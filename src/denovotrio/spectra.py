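"""Mutation-type spectra, distance-stratified comparisons and motif tests.

SNVs are typed on a collapsed strand so that complementary changes coincide
(C→T is the same event as G→A): records whose reference base is G or T are
reverse-complemented before typing, leaving six changes
{A→C, A→G, A→T, C→A, C→G, C→T}.  The flanking triplet is reported on the
collapsed strand.  Context classes follow the rate analyses: CpG (a C
directly 5' of G, on either strand), non-CpG strong (C/G) and weak (A/T).

Spectra are compared with Fisher's exact test — exact for 2×2 tables,
seeded Monte-Carlo over the margin-conditional distribution for 2×k.
Motif analyses cover the APOBEC-preferred TCW context (W = A/T), the
broader DCH context (D = A/G/T, H = A/C/T: a cytosine neither preceded by C
nor followed by G) and the CpG fraction of C→T transitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import fisher_exact

from .core import (
    CONTEXT_CPG,
    CONTEXT_STRONG,
    CONTEXT_WEAK,
    KIND_SNV,
    GenomeModel,
    revcomp,
)
from .rates import wilson_ci

COLLAPSED_CHANGES = ("A→C", "A→G", "A→T", "C→A", "C→G", "C→T")
TRANSITIONS = {"A→G", "C→T"}


@dataclass(frozen=True)
class MutationType:
    change: str            # one of COLLAPSED_CHANGES
    context_class: str     # CpG / strong / weak
    triplet: str | None    # 5'-site-3' on the collapsed strand

    @property
    def is_transition(self) -> bool:
        return self.change in TRANSITIONS


def classify_mutation(chrom: str, pos: int, ref: str, alt: str,
                      genome: GenomeModel) -> MutationType:
    """Type an SNV on the collapsed (A/C-reference) strand."""
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValueError("classify_mutation expects an SNV")
    tri = genome.triplet(chrom, pos)
    if genome.base(chrom, pos) != ref:
        raise ValueError(f"reference mismatch at {chrom}:{pos}")
    if ref in "GT":
        ref_c, alt_c = revcomp(ref), revcomp(alt)
        tri_c = revcomp(tri) if tri is not None else None
    else:
        ref_c, alt_c, tri_c = ref, alt, tri
    change = f"{ref_c}→{alt_c}"
    if ref_c == "A":
        ctx = CONTEXT_WEAK
    else:
        # CpG status from the collapsed-strand 3' neighbour
        if tri_c is not None:
            ctx = CONTEXT_CPG if tri_c[2] == "G" else CONTEXT_STRONG
        else:
            cls = genome.context_class(chrom, pos)
            ctx = cls if cls is not None else CONTEXT_STRONG
    return MutationType(change=change, context_class=ctx, triplet=tri_c)


def classify_calls(calls: pd.DataFrame, genome: GenomeModel) -> pd.DataFrame:
    """Attach collapsed change / context / triplet columns to SNV calls.

    Calls whose triplet contains an N keep ``triplet = None`` and are
    excluded from motif analyses downstream.
    """
    snvs = calls[calls["kind"] == KIND_SNV].copy()
    typed = [classify_mutation(c, int(p), r, a, genome)
             for c, p, r, a in zip(snvs["chrom"], snvs["pos"],
                                   snvs["ref_allele"], snvs["alt_allele"])]
    snvs["change"] = [t.change for t in typed]
    snvs["context_class"] = [t.context_class for t in typed]
    snvs["triplet"] = [t.triplet for t in typed]
    return snvs


# ---------------------------------------------------------------------------
# distance-stratified spectra
# ---------------------------------------------------------------------------

# default strata over the nearest same-individual distance, in bp:
# tandem, 2-10, 10-100, 100-2000, 2000-20000, and non-clustered (>= 20 kb)
DEFAULT_BIN_EDGES = (1, 10, 100, 2000, 20_000)


def nearest_same_individual_distance(mutations: pd.DataFrame) -> np.ndarray:
    """Bidirectional nearest same-individual distance per mutation (inf if
    the individual has no other mutation)."""
    pos = mutations["concat_pos"].to_numpy(np.int64)
    ind = mutations["individual_id"].to_numpy()
    order = np.lexsort((pos, ind))
    p, g = pos[order], ind[order]
    gaps = p[1:] - p[:-1]
    same = g[1:] == g[:-1]
    fwd = np.full(p.size, np.inf)
    bwd = np.full(p.size, np.inf)
    fwd[:-1][same] = gaps[same]
    bwd[1:][same] = gaps[same]
    nearest = np.minimum(fwd, bwd)
    out = np.empty(p.size)
    out[order] = nearest
    return out


def distance_stratum_labels(distances: np.ndarray,
                            edges=DEFAULT_BIN_EDGES) -> np.ndarray:
    """Stratum label per mutation from its nearest same-individual distance."""
    labels = np.empty(distances.size, dtype=object)
    e = list(edges)
    for i, d in enumerate(distances):
        if d <= e[0]:
            labels[i] = f"={e[0]}"
        elif d >= e[-1] or np.isinf(d):
            labels[i] = f">={e[-1]}"
        else:
            for lo, hi in zip(e[:-1], e[1:]):
                if lo < d <= hi:
                    labels[i] = f"({lo},{hi}]"
                    break
    return labels


@dataclass
class SpectrumTable:
    stratum: str
    counts: pd.Series          # per collapsed change
    proportions: pd.DataFrame  # proportion with Wilson CI per change


def spectrum_table(snvs: pd.DataFrame, stratum: str) -> SpectrumTable:
    counts = snvs["change"].value_counts().reindex(COLLAPSED_CHANGES,
                                                   fill_value=0)
    total = int(counts.sum())
    rows = []
    for change in COLLAPSED_CHANGES:
        n = int(counts[change])
        if total:
            low, high = wilson_ci(n, total)
            rows.append((change, n / total, low, high))
        else:
            rows.append((change, 0.0, 0.0, 0.0))
    props = pd.DataFrame(rows, columns=["change", "proportion",
                                        "ci_low", "ci_high"])
    return SpectrumTable(stratum=stratum, counts=counts, proportions=props)


def spectrum_by_distance_bin(typed_snvs: pd.DataFrame,
                             edges=DEFAULT_BIN_EDGES) -> list[SpectrumTable]:
    """Per-stratum spectra over nearest same-individual distance bins.

    Empty strata are reported with zero counts rather than dropped.
    """
    dist = nearest_same_individual_distance(typed_snvs)
    labels = distance_stratum_labels(dist, edges)
    e = list(edges)
    stratum_order = [f"={e[0]}"] + \
        [f"({lo},{hi}]" for lo, hi in zip(e[:-1], e[1:])] + [f">={e[-1]}"]
    tables = []
    for stratum in stratum_order:
        tables.append(spectrum_table(typed_snvs[labels == stratum], stratum))
    return tables


# ---------------------------------------------------------------------------
# Fisher comparisons
# ---------------------------------------------------------------------------

def _table_log_prob(table: np.ndarray) -> float:
    """Log conditional probability of a 2xk table given all margins."""
    n = table.sum()
    return (gammaln(table.sum(axis=1) + 1).sum()
            + gammaln(table.sum(axis=0) + 1).sum()
            - gammaln(n + 1) - gammaln(table + 1).sum())


def compare_spectra(counts_a, counts_b, draws: int = 100_000,
                    seed: int = 0) -> dict:
    """Fisher's exact test on a 2xk table of type counts.

    2x2 tables use the exact hypergeometric test; wider tables use seeded
    Monte-Carlo over the margin-conditional distribution (probability-based
    two-sided p, add-one corrected).  The method used is reported.
    """
    a = np.asarray(counts_a, dtype=np.int64)
    b = np.asarray(counts_b, dtype=np.int64)
    if a.sum() == 0 and b.sum() == 0:
        raise ValueError("both count vectors are all-zero")
    keep = (a + b) > 0
    a, b = a[keep], b[keep]
    table = np.vstack([a, b])
    if table.shape[1] <= 2:
        if table.shape[1] == 1:
            return {"p_value": 1.0, "method": "degenerate"}
        _, p = fisher_exact(table)
        return {"p_value": float(p), "method": "exact"}
    rng = np.random.default_rng(seed)
    obs_lp = _table_log_prob(table)
    col = np.repeat(np.arange(table.shape[1]), table.sum(axis=0))
    n_a = int(a.sum())
    hits = 0
    for _ in range(draws):
        perm = rng.permutation(col)
        ca = np.bincount(perm[:n_a], minlength=table.shape[1])
        sim = np.vstack([ca, table.sum(axis=0) - ca])
        if _table_log_prob(sim) <= obs_lp + 1e-9:
            hits += 1
    return {"p_value": (1 + hits) / (1 + draws),
            "method": f"monte-carlo({draws})"}


# ---------------------------------------------------------------------------
# tandem polymerase-zeta signature
# ---------------------------------------------------------------------------

# dinucleotide changes characteristic of polymerase-zeta errors, plus-strand
POLZETA_SIGNATURES = {("GC", "AA"), ("GC", "TT"), ("GA", "TT"), ("TC", "AA")}


def is_polzeta_signature(ref_dinuc: str, alt_dinuc: str,
                         positions: tuple[int, int] | None = None) -> bool:
    """True iff a tandem dinucleotide change is GC→AA or GA→TT on either
    strand (plus-strand set {GC→AA, GC→TT, GA→TT, TC→AA})."""
    if positions is not None and abs(positions[1] - positions[0]) != 1:
        raise ValueError("polymerase-zeta signature applies to adjoining pairs")
    if len(ref_dinuc) != 2 or len(alt_dinuc) != 2:
        raise ValueError("expected dinucleotide alleles")
    return (ref_dinuc, alt_dinuc) in POLZETA_SIGNATURES or \
        (revcomp(ref_dinuc), revcomp(alt_dinuc)) in POLZETA_SIGNATURES


def polzeta_fraction(tandem_event_frames: list[pd.DataFrame]) -> dict:
    """Fraction of tandem pair events matching the polymerase-zeta signature."""
    n_pairs = 0
    n_sig = 0
    for ev in tandem_event_frames:
        if len(ev) != 2:
            continue
        ev = ev.sort_values("pos")
        ref = "".join(ev["ref_allele"])
        alt = "".join(ev["alt_allele"])
        n_pairs += 1
        n_sig += is_polzeta_signature(ref, alt)
    frac = n_sig / n_pairs if n_pairs else 0.0
    low, high = wilson_ci(n_sig, n_pairs) if n_pairs else (0.0, 0.0)
    return {"n_signature": n_sig, "n_pairs": n_pairs, "fraction": frac,
            "ci_low": low, "ci_high": high}


# ---------------------------------------------------------------------------
# motif tests
# ---------------------------------------------------------------------------

def matches_tcw(triplet: str) -> bool:
    """T-C-(A|T): the APOBEC deamination context (collapsed strand)."""
    return (len(triplet) == 3 and triplet[0] == "T" and triplet[1] == "C"
            and triplet[2] in "AT")


def matches_dch(triplet: str) -> bool:
    """D-C-H with D=A/G/T and H=A/C/T: C neither preceded by C nor followed
    by G (collapsed strand)."""
    return (len(triplet) == 3 and triplet[1] == "C"
            and triplet[0] in "AGT" and triplet[2] in "ACT")


def motif_tests(typed_snvs: pd.DataFrame,
                clustered_range: tuple[int, int] = (10, 20_000),
                seed: int = 0) -> dict:
    """Motif enrichment of clustered (10 bp – 20 kb) vs non-clustered SNVs.

    For C→G and C→T mutations, reports the fraction matching the TCW and
    DCH motifs and (for C→T) the CpG fraction, per group, with Wilson CIs
    and an exact 2×2 Fisher comparison.  Mutations with an undefined
    triplet are excluded and counted in the QC tally.
    """
    dist = nearest_same_individual_distance(typed_snvs)
    lo, hi = clustered_range
    group = np.where((dist > lo) & (dist < hi), "clustered",
                     np.where(dist >= hi, "non-clustered", "near"))
    usable = typed_snvs["triplet"].notna().to_numpy()
    report: dict = {"n_excluded_no_context": int((~usable).sum()),
                    "tests": {}}

    def one_test(name: str, mask_change: np.ndarray, matcher) -> None:
        rows = {}
        table = np.zeros((2, 2), dtype=int)
        for gi, gname in enumerate(("clustered", "non-clustered")):
            sel = usable & mask_change & (group == gname)
            trips = typed_snvs.loc[sel, "triplet"]
            n = int(sel.sum())
            hits = int(sum(matcher(t) for t in trips))
            if n:
                low, high = wilson_ci(hits, n)
            else:
                low = high = 0.0
            rows[gname] = {"n": n, "matching": hits,
                           "fraction": hits / n if n else 0.0,
                           "ci_low": low, "ci_high": high}
            table[gi] = (hits, n - hits)
        p = fisher_exact(table)[1] if table.sum() else 1.0
        report["tests"][name] = {"groups": rows, "p_value": float(p)}

    is_cg = (typed_snvs["change"] == "C→G").to_numpy()
    is_ct = (typed_snvs["change"] == "C→T").to_numpy()
    one_test("TCW_of_C>G", is_cg, matches_tcw)
    one_test("TCW_of_C>T", is_ct, matches_tcw)
    one_test("DCH_of_C>G", is_cg, matches_dch)
    one_test("CpG_of_C>T", is_ct,
             lambda t: len(t) == 3 and t[1] == "C" and t[2] == "G")
    return report
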