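"""Multiple sequence alignment statistics.

Implements the gap-filtering cascade used before coevolutionary analysis —
drop sequences with more than 50% gaps, keep only columns with less than 30%
gaps, then drop sequences with more than 70% gaps in the retained columns —
and per-column Shannon entropy profiles.

Entropy is computed over the non-gap symbols of each column,
S_i = -sum_a f_i(a) ln f_i(a) with f_i normalized over non-gap counts, in
nats, so 0 <= S_i <= ln 20.  Mutated sites are classified "low" or "high"
relative to the mean entropy over the mutated sites themselves (ties at the
mean count as low).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .structure_io import AMINO_ACIDS

__all__ = [
    "MSA",
    "EntropyProfile",
    "read_msa",
    "write_msa",
    "filter_sequences",
    "select_columns",
    "filter_cascade",
    "entropy_profile",
    "classify_sites",
    "GAP",
]

log = logging.getLogger(__name__)

GAP = "-"
ALPHABET = AMINO_ACIDS + GAP


@dataclass
class MSA:
    """Aligned sequences over the 20 amino acids plus the gap symbol.

    ``columns`` maps local column index -> original (1-based) column number,
    so entropy sites can be addressed in wild-type numbering after column
    selection.
    """

    ids: list[str]
    matrix: np.ndarray  # (n_sequences, L) array of single characters
    columns: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="<U1")
        if self.matrix.ndim != 2:
            raise ValueError("alignment matrix must be 2-D")
        if len(self.ids) != self.matrix.shape[0]:
            raise ValueError("id count must match sequence count")
        if not self.columns:
            self.columns = list(range(1, self.matrix.shape[1] + 1))
        if len(self.columns) != self.matrix.shape[1]:
            raise ValueError("column mapping length must match width")
        unknown = ~np.isin(self.matrix, list(ALPHABET))
        if unknown.any():
            log.warning("mapping %d unknown symbols to gap", int(unknown.sum()))
            self.matrix[unknown] = GAP

    @property
    def n_sequences(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def gap_fraction_per_sequence(self) -> np.ndarray:
        return (self.matrix == GAP).mean(axis=1)

    def gap_fraction_per_column(self) -> np.ndarray:
        return (self.matrix == GAP).mean(axis=0)


def read_msa(path: str | Path, fmt: str | None = None) -> MSA:
    """Read a FASTA or Stockholm alignment (format inferred from suffix)."""
    path = Path(path)
    if fmt is None:
        fmt = "stockholm" if path.suffix.lower() in (".sto", ".stk", ".stockholm") else "fasta"
    try:
        aln = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise ValueError(f"{path}: cannot read as {fmt} alignment ({exc})") from exc
    ids = [rec.id for rec in aln]
    matrix = np.array([list(str(rec.seq).upper().replace(".", GAP)) for rec in aln])
    return MSA(ids=ids, matrix=matrix)


def write_msa(msa: MSA, path: str | Path, fmt: str = "fasta") -> None:
    records = [
        SeqRecord(Seq("".join(row)), id=sid, description="")
        for sid, row in zip(msa.ids, msa.matrix)
    ]
    AlignIO.write(MultipleSeqAlignment(records), str(path), fmt)


def filter_sequences(msa: MSA, max_gap_fraction: float) -> MSA:
    """Remove sequences whose gap fraction exceeds ``max_gap_fraction``."""
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise ValueError("max_gap_fraction must be in [0, 1]")
    keep = msa.gap_fraction_per_sequence() <= max_gap_fraction
    if not keep.any():
        raise ValueError("sequence filter removed every sequence")
    return MSA(
        ids=[sid for sid, k in zip(msa.ids, keep) if k],
        matrix=msa.matrix[keep],
        columns=list(msa.columns),
    )


def select_columns(msa: MSA, max_gap_fraction: float) -> MSA:
    """Keep only columns with gap fraction strictly below ``max_gap_fraction``.

    The returned alignment's ``columns`` maps back to the original column
    numbering.
    """
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise ValueError("max_gap_fraction must be in [0, 1]")
    keep = msa.gap_fraction_per_column() < max_gap_fraction
    if not keep.any():
        raise ValueError("column selection removed every column")
    return MSA(
        ids=list(msa.ids),
        matrix=msa.matrix[:, keep],
        columns=[c for c, k in zip(msa.columns, keep) if k],
    )


def filter_cascade(
    msa: MSA,
    seq_gap_first: float = 0.5,
    col_gap: float = 0.3,
    seq_gap_second: float = 0.7,
) -> MSA:
    """Sequence filter (>50% gaps), column selection (<30% gaps), then a
    second sequence filter (>70% gaps) on the retained columns."""
    out = filter_sequences(msa, seq_gap_first)
    out = select_columns(out, col_gap)
    return filter_sequences(out, seq_gap_second)


@dataclass
class EntropyProfile:
    """Per-column Shannon entropy in nats; NaN marks all-gap columns."""

    entropies: np.ndarray
    gap_fractions: np.ndarray
    columns: list[int]

    def __post_init__(self) -> None:
        finite = self.entropies[np.isfinite(self.entropies)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > math.log(20) + 1e-9):
            raise ValueError("entropies must lie in [0, ln 20]")

    def at_column(self, original_column: int) -> float:
        try:
            idx = self.columns.index(original_column)
        except ValueError:
            raise KeyError(f"column {original_column} not in retained set") from None
        return float(self.entropies[idx])


def entropy_profile(msa: MSA) -> EntropyProfile:
    """Shannon entropy per column over non-gap symbol frequencies."""
    if msa.n_sequences == 0:
        raise ValueError("empty alignment")
    ents = np.empty(msa.length)
    for j in range(msa.length):
        col = msa.matrix[:, j]
        col = col[col != GAP]
        if col.size == 0:
            ents[j] = np.nan
            continue
        _, counts = np.unique(col, return_counts=True)
        f = counts / counts.sum()
        ents[j] = float(-(f * np.log(f)).sum())
    return EntropyProfile(
        entropies=ents,
        gap_fractions=msa.gap_fraction_per_column(),
        columns=list(msa.columns),
    )


def classify_sites(
    profile: EntropyProfile, site_positions: list[int]
) -> tuple[dict[int, str], float, list[int]]:
    """Label each mutated site low/high against the mean entropy of the sites.

    Sites outside the retained columns (or falling on all-gap columns) are
    excluded and reported back.  A site at exactly the mean is "low".
    Returns (labels, mean entropy, excluded sites).
    """
    if not site_positions:
        raise ValueError("site list must be non-empty")
    values: dict[int, float] = {}
    excluded: list[int] = []
    for pos in site_positions:
        try:
            v = profile.at_column(pos)
        except KeyError:
            excluded.append(pos)
            continue
        if not np.isfinite(v):
            excluded.append(pos)
            continue
        values[pos] = v
    if not values:
        raise ValueError("no site falls on a retained column")
    mean = float(np.mean(list(values.values())))
    labels = {pos: ("low" if v <= mean else "high") for pos, v in values.items()}
    return labels, mean, excluded
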