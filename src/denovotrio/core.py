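"""Shared domain types and file I/O for the trio de novo pipeline.

The working containers are deliberately plain: a genome is a dict of numpy
byte arrays, a pedigree is a pandas DataFrame, and a set of mutation calls is
a DataFrame with one row per event.  Every module in the package exchanges
these objects.

Sequence context vocabulary
---------------------------
Autosomal sites are partitioned into three classes used throughout the
mutation-rate and spectrum analyses:

* ``CpG``    -- a C immediately followed by G, or the G of such a pair.
* ``strong`` -- C or G outside a CpG dinucleotide (three hydrogen bonds).
* ``weak``   -- A or T (two hydrogen bonds).

Positions are 1-based everywhere except BED/bedGraph intervals, which are
half-open 0-based as those formats require.  The "concatenated axis" places
chromosomes end to end in karyotype order with no gap, so that distances
between mutations are defined genome-wide by a single integer coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pyfaidx

# context class labels, in the order used for coded arrays
CONTEXT_CPG = "CpG"
CONTEXT_STRONG = "strong"
CONTEXT_WEAK = "weak"
CONTEXT_CLASSES = (CONTEXT_CPG, CONTEXT_STRONG, CONTEXT_WEAK)

# integer codes for vectorised work; -1 marks N / undefined
CONTEXT_CODE = {CONTEXT_CPG: 0, CONTEXT_STRONG: 1, CONTEXT_WEAK: 2}
CODE_CONTEXT = {v: k for k, v in CONTEXT_CODE.items()}

_A, _C, _G, _T, _N = (ord(b) for b in "ACGTN")

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(s: str) -> str:
    """Reverse complement of a nucleotide string."""
    return "".join(COMPLEMENT[b] for b in reversed(s))


@dataclass
class GenomeModel:
    """A reference genome held in memory as ASCII byte arrays.

    Parameters
    ----------
    chrom_names
        Chromosome labels in karyotype order; this order defines the
        concatenated coordinate axis.
    sequence
        Mapping from chromosome name to a ``uint8`` array of ASCII codes
        over the alphabet ``{A, C, G, T, N}``.
    """

    chrom_names: list[str]
    sequence: dict[str, np.ndarray]
    _context: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for name in self.chrom_names:
            seq = self.sequence[name]
            if seq.size == 0:
                raise ValueError(f"chromosome {name!r} has zero length")
            bad = ~np.isin(seq, [_A, _C, _G, _T, _N])
            if bad.any():
                raise ValueError(f"chromosome {name!r} contains non-ACGTN bytes")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: int(self.sequence[c].size) for c in self.chrom_names}

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def concat_offsets(self) -> dict[str, int]:
        """0-based start of each chromosome on the concatenated axis."""
        offsets, cum = {}, 0
        for c in self.chrom_names:
            offsets[c] = cum
            cum += self.sequence[c].size
        return offsets

    def context_codes(self, chrom: str) -> np.ndarray:
        """Per-position context codes (0=CpG, 1=strong, 2=weak, -1=N)."""
        if chrom not in self._context:
            seq = self.sequence[chrom]
            is_c = seq == _C
            is_g = seq == _G
            cpg = np.zeros(seq.size, dtype=bool)
            cpg[:-1] = is_c[:-1] & is_g[1:]       # the C of CG
            cpg[1:] |= is_c[:-1] & is_g[1:]       # the G of CG
            codes = np.full(seq.size, -1, dtype=np.int8)
            codes[(seq == _A) | (seq == _T)] = CONTEXT_CODE[CONTEXT_WEAK]
            codes[is_c | is_g] = CONTEXT_CODE[CONTEXT_STRONG]
            codes[cpg] = CONTEXT_CODE[CONTEXT_CPG]
            self._context[chrom] = codes
        return self._context[chrom]

    def context_class(self, chrom: str, pos: int) -> str | None:
        """Context class of a 1-based position, or None at an N."""
        code = int(self.context_codes(chrom)[pos - 1])
        return CODE_CONTEXT.get(code)

    def base(self, chrom: str, pos: int) -> str:
        return chr(self.sequence[chrom][pos - 1])

    def triplet(self, chrom: str, pos: int) -> str | None:
        """5'-base, site, 3'-base around a 1-based position.

        Returns None at a chromosome edge or when any base is N.
        """
        seq = self.sequence[chrom]
        if pos < 2 or pos > seq.size - 1:
            return None
        tri = seq[pos - 2:pos + 1].tobytes().decode()
        return None if "N" in tri else tri

    def context_counts(self) -> dict[str, int]:
        """Genome-wide number of positions per context class."""
        totals = dict.fromkeys(CONTEXT_CLASSES, 0)
        for c in self.chrom_names:
            codes = self.context_codes(c)
            for name, code in CONTEXT_CODE.items():
                totals[name] += int((codes == code).sum())
        return totals

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for c in self.chrom_names:
                fh.write(f">{c}\n")
                s = self.sequence[c].tobytes().decode()
                for i in range(0, len(s), width):
                    fh.write(s[i:i + width] + "\n")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeModel":
        fa = pyfaidx.Fasta(str(path))
        names = list(fa.keys())
        seqs = {
            n: np.frombuffer(str(fa[n][:]).upper().encode(), dtype=np.uint8).copy()
            for n in names
        }
        return cls(chrom_names=names, sequence=seqs)


@dataclass(frozen=True)
class Family:
    """A sequenced parent-offspring trio.

    ``father_age`` / ``mother_age`` are the parental ages at the proband's
    conception in years (the generation intervals p_f and m_f entering the
    per-year rate denominator).
    """

    family_id: str
    proband_id: str
    father_id: str
    mother_id: str
    father_age: float
    mother_age: float

    def __post_init__(self) -> None:
        if self.father_age <= 0 or self.mother_age <= 0:
            raise ValueError("parental ages must be positive")


PEDIGREE_COLUMNS = [
    "family_id", "proband_id", "father_id", "mother_id",
    "father_age", "mother_age",
]


def families_to_frame(families: list[Family]) -> pd.DataFrame:
    return pd.DataFrame([f.__dict__ for f in families], columns=PEDIGREE_COLUMNS)


def frame_to_families(df: pd.DataFrame) -> list[Family]:
    return [Family(**{k: row[k] for k in PEDIGREE_COLUMNS})
            for _, row in df.iterrows()]


def write_pedigree(families: list[Family], path: str | Path) -> None:
    families_to_frame(families).to_csv(path, sep="\t", index=False)


def read_pedigree(path: str | Path) -> list[Family]:
    return frame_to_families(pd.read_csv(path, sep="\t", dtype={"family_id": str,
                                                                "proband_id": str,
                                                                "father_id": str,
                                                                "mother_id": str}))


# ---------------------------------------------------------------------------
# Mutation call tables
# ---------------------------------------------------------------------------

KIND_SNV = "SNV"
KIND_INS = "insertion"
KIND_DEL = "deletion"

CALL_COLUMNS = [
    "chrom", "pos", "ref_allele", "alt_allele", "kind",
    "family_id", "individual_id", "context_class", "concat_pos",
]


def classify_kind(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return KIND_SNV
    return KIND_INS if len(alt) > len(ref) else KIND_DEL


def add_concat_pos(calls: pd.DataFrame, genome: GenomeModel) -> pd.DataFrame:
    """Attach the concatenated-axis coordinate and sort by it."""
    offsets = genome.concat_offsets()
    out = calls.copy()
    out["concat_pos"] = out["chrom"].map(offsets).astype(np.int64) + out["pos"].astype(np.int64)
    return out.sort_values("concat_pos", kind="mergesort").reset_index(drop=True)


def annotate_context(calls: pd.DataFrame, genome: GenomeModel) -> pd.DataFrame:
    """Attach the reference context class of each call site."""
    out = calls.copy()
    ctx = [
        genome.context_class(c, int(p))
        for c, p in zip(out["chrom"], out["pos"])
    ]
    out["context_class"] = ctx
    return out


def write_calls(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t",
                       dtype={"chrom": str, "family_id": str, "individual_id": str})
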