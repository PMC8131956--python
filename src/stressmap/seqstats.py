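"""Mutational-scan bookkeeping, ddG consensus, alignment entropy, APR consensus.

The free-energy tables themselves are produced externally (FoldX- or
Rosetta-style scans); this module enumerates the mutation universe, reads
the tables, and intersects their stabilizing calls.  Sign convention:
negative ddG = stabilizing, declared in the CSV header and validated on
read.  Alignment entropy is Shannon entropy in nats over the 21-symbol
alphabet (20 amino acids + gap), so a maximally diverse column scores
ln 21 ~ 3.04 and a conserved column 0.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import ConfigError, DegenerateInputError, ShapeError
from .structure_io import AprSet

__all__ = [
    "AMINO_ACIDS",
    "AlignmentProfile",
    "PredictorMask",
    "ConsensusResult",
    "enumerate_single_mutants",
    "read_ddg_csv",
    "write_ddg_csv",
    "stabilizing_consensus",
    "column_entropy",
    "apr_consensus",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET21 = AMINO_ACIDS + "-"
#: Header comment a ddG CSV must carry to declare its sign convention.
DDG_CONVENTION_LINE = "# ddg_convention: negative=stabilizing"


@dataclass
class AlignmentProfile:
    """Per-column symbol counts (21 x L) and Shannon entropy in nats."""

    counts: pd.DataFrame         # index: symbols, columns: 0..L-1
    entropy: np.ndarray          # (L,) nats, in [0, ln 21]

    @property
    def n_columns(self) -> int:
        return int(self.entropy.size)

    @property
    def max_entropy(self) -> float:
        return math.log(len(_ALPHABET21))


@dataclass
class PredictorMask:
    """One APR predictor's per-residue boolean call."""

    name: str
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, bool)
        if self.calls.ndim != 1:
            raise ShapeError("predictor mask must be 1-D")


@dataclass
class ConsensusResult:
    set_a: Set[str]
    set_b: Set[str]
    intersection: Set[str]
    frac_a: float
    frac_b: float
    frac_both: float
    n_universe: int


# ---------------------------------------------------------------------------
# Mutational scan
# ---------------------------------------------------------------------------

def enumerate_single_mutants(sequence: str) -> List[str]:
    """All 19 * len(sequence) single substitutions as ids like "K1A".

    A 442-residue sequence yields exactly 8398 mutations.
    """
    seq = str(sequence).strip().upper()
    muts: List[str] = []
    for pos, wt in enumerate(seq, start=1):
        if wt not in AMINO_ACIDS:
            raise ConfigError(f"non-standard amino acid {wt!r} at position {pos}")
        for mut in AMINO_ACIDS:
            if mut != wt:
                muts.append(f"{wt}{pos}{mut}")
    return muts


def write_ddg_csv(table: pd.DataFrame, path) -> None:
    """Write a ddG table with the sign-convention declaration header."""
    with open(path, "w") as fh:
        fh.write(DDG_CONVENTION_LINE + "\n")
        table.to_csv(fh, index=False)


def read_ddg_csv(source) -> pd.DataFrame:
    """Read a ddG CSV (columns position, wt, mut, ddg[, source]).

    The first line must declare the sign convention
    ``# ddg_convention: negative=stabilizing``; tables without it are
    rejected so a flipped-sign scan can never be silently intersected.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        try:
            with open(source) as fh:
                text = fh.read()
        except (OSError, ValueError):
            text = str(source)
    lines = text.splitlines()
    if not lines or lines[0].strip().replace(" ", "") != \
            DDG_CONVENTION_LINE.replace(" ", ""):
        raise ConfigError(
            f"ddG CSV must declare its sign convention in the first line: "
            f"{DDG_CONVENTION_LINE!r}")
    df = pd.read_csv(io.StringIO("\n".join(lines[1:])))
    required = {"position", "wt", "mut", "ddg"}
    if not required.issubset(df.columns):
        raise ConfigError(f"ddG CSV missing columns {sorted(required - set(df.columns))}")
    if (df["wt"] == df["mut"]).any():
        bad = df[df["wt"] == df["mut"]].iloc[0]
        raise ConfigError(f"mutant equals wild-type at position {bad['position']}")
    df["mutation"] = df["wt"].astype(str) + df["position"].astype(str) + \
        df["mut"].astype(str)
    return df


def stabilizing_consensus(
    a: pd.DataFrame,
    b: pd.DataFrame,
    threshold: float = 0.0,
) -> ConsensusResult:
    """Stabilizing sets of two ddG tables and their intersection.

    A mutation is stabilizing iff ddg < threshold (strict).  Both tables
    must cover the same mutation universe; fractions are relative to the
    universe size.
    """
    ids_a = set(a["mutation"])
    ids_b = set(b["mutation"])
    if ids_a != ids_b:
        missing_in_b = sorted(ids_a - ids_b)[:10]
        missing_in_a = sorted(ids_b - ids_a)[:10]
        raise ConfigError(
            f"mutation universes differ; e.g. missing in b: {missing_in_b}, "
            f"missing in a: {missing_in_a}")
    n = len(ids_a)
    if n == 0:
        raise DegenerateInputError("empty mutation universe")
    set_a = set(a.loc[a["ddg"] < threshold, "mutation"])
    set_b = set(b.loc[b["ddg"] < threshold, "mutation"])
    inter = set_a & set_b
    return ConsensusResult(set_a, set_b, inter,
                           len(set_a) / n, len(set_b) / n, len(inter) / n, n)


# ---------------------------------------------------------------------------
# Alignment entropy
# ---------------------------------------------------------------------------

def column_entropy(alignment) -> AlignmentProfile:
    """Shannon entropy per alignment column over 21 symbols (nats).

    ``alignment`` is aligned-FASTA text, a path, or an open handle.  Gap-only
    columns are single-symbol columns with H = 0.  Ragged alignments and
    unknown symbols raise.
    """
    if hasattr(alignment, "read"):
        handle = alignment
    else:
        text = str(alignment)
        if "\n" in text or text.lstrip().startswith(">"):
            handle = io.StringIO(text)
        else:
            handle = open(text)
    records = list(SeqIO.parse(handle, "fasta"))
    if not records:
        raise DegenerateInputError("no sequences in alignment")
    length = len(records[0].seq)
    seqs = []
    for rec in records:
        s = str(rec.seq).upper().replace(".", "-")
        if len(s) != length:
            raise ShapeError(
                f"ragged alignment: {rec.id} has length {len(s)}, expected {length}")
        bad = set(s) - set(_ALPHABET21)
        if bad:
            raise ConfigError(f"unknown symbols {sorted(bad)} in sequence {rec.id}")
        seqs.append(s)

    mat = np.array([list(s) for s in seqs])
    counts = np.zeros((len(_ALPHABET21), length), dtype=int)
    for si, sym in enumerate(_ALPHABET21):
        counts[si] = (mat == sym).sum(axis=0)
    p = counts / counts.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log(p), 0.0)
    entropy = terms.sum(axis=0)
    df = pd.DataFrame(counts, index=list(_ALPHABET21))
    return AlignmentProfile(df, entropy)


# ---------------------------------------------------------------------------
# APR consensus
# ---------------------------------------------------------------------------

def apr_consensus(masks: Sequence[PredictorMask], min_agree: int = 3) -> AprSet:
    """Residues called by >= ``min_agree`` predictors, as maximal intervals.

    Positions are 1-based; interval names are "start-end".
    """
    if min_agree > len(masks):
        raise ConfigError(
            f"min_agree={min_agree} exceeds the {len(masks)} available masks")
    if not masks:
        raise DegenerateInputError("no predictor masks")
    length = masks[0].calls.size
    for m in masks[1:]:
        if m.calls.size != length:
            raise ShapeError(f"mask {m.name} length {m.calls.size} != {length}")
    votes = np.sum([m.calls for m in masks], axis=0)
    selected = votes >= min_agree

    regions: Dict[str, Tuple[int, int]] = {}
    start = None
    for pos in range(length + 1):
        on = pos < length and selected[pos]
        if on and start is None:
            start = pos
        elif not on and start is not None:
            lo, hi = start + 1, pos          # 1-based inclusive
            regions[f"{lo}-{hi}"] = (lo, hi)
            start = None
    return AprSet(regions)
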