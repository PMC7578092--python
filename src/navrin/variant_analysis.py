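"""Variant catalogue handling and node-frequency analysis.

The node-frequency analysis contrasts pathogenic (PAT) and neutral (NEUTRAL)
RIN ensembles position by position: the frequency of a node label l within a
group is the fraction of that group's networks in which residue l carries at
least one non-covalent edge.  Frequency 1 means the residue is bonded in
every network of the group; frequency 0 means it never forms a non-covalent
contact.  Divergent intervals between the two group profiles flag sequence
regions whose contact behaviour differs between pathogenic and neutral
variants.

Domain coordinates of the sodium-channel alpha-subunit (wild-type numbering,
1-based inclusive): DI 112-410, DII 715-978, DIII 1169-1477, DIV 1488-1784;
positions outside every domain are linkers.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .rin import RIN
from .structure_io import MutationSpec, parse_mutation

__all__ = [
    "VariantRecord",
    "FrequencyProfile",
    "DomainMap",
    "DEFAULT_DOMAIN_MAP",
    "load_catalogue",
    "packaged_catalogue_path",
    "node_frequency",
    "frequency_contrast",
    "locate_domain",
]

CLASSES = ("PAT", "NEUTRAL")
SUBTYPES = ("IEM", "SFN", "PEPD", "PDN", "nABN", "dbSNP", "pseudo")


@dataclass(frozen=True)
class VariantRecord:
    id: int
    mutation: MutationSpec
    cls: str
    subtype: str
    human: bool = True

    def __post_init__(self) -> None:
        if self.cls not in CLASSES:
            raise ValueError(f"variant {self.id}: unknown class {self.cls!r}")
        if self.subtype not in SUBTYPES:
            raise ValueError(f"variant {self.id}: unknown subtype {self.subtype!r}")


@dataclass
class DomainMap:
    """Named, non-overlapping, ascending 1-based inclusive intervals."""

    intervals: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        prev_end = 0
        for name, (lo, hi) in self.intervals.items():
            if lo > hi or lo <= prev_end:
                raise ValueError(f"domain {name}: intervals must be ascending, non-overlapping")
            prev_end = hi


DEFAULT_DOMAIN_MAP = DomainMap(
    intervals={"DI": (112, 410), "DII": (715, 978), "DIII": (1169, 1477), "DIV": (1488, 1784)}
)


def locate_domain(position: int, domain_map: DomainMap | None = None) -> str:
    """Containing domain name for a sequence position, else ``"linker"``."""
    if position < 1:
        raise ValueError("position must be >= 1")
    dm = domain_map or DEFAULT_DOMAIN_MAP
    for name, (lo, hi) in dm.intervals.items():
        if lo <= position <= hi:
            return name
    return "linker"


def packaged_catalogue_path() -> Path:
    """Path to the packaged synthetic variant catalogue.

    The catalogue reproduces the study's layout exactly — 85 variants, ids
    0-84, pathogenic ids 0-30 (18 IEM, 6 SFN, 6 PEPD, 1 PDN) followed by 54
    neutral ids 31-84 (4 nABN, 17 dbSNP, 33 pseudo) — anchored on the
    variants named in the study text (I136V, A863P at id 11, T1596I at id
    30, M1532I pathogenic, M1532V neutral); the remaining entries are
    synthetic placeholder substitutions, not a transcription of the
    published figure.
    """
    return Path(resources.files("navrin") / "data" / "variant_catalogue_synthetic.tsv")


def load_catalogue(path: str | Path | None = None) -> list[VariantRecord]:
    """Load and validate a variant catalogue TSV.

    Columns: id, mutation, class, subtype, human_flag.  Ids must be unique
    and contiguous from 0, with all PAT records preceding all NEUTRAL ones.
    """
    path = Path(path) if path is not None else packaged_catalogue_path()
    records: list[VariantRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for rownum, row in enumerate(reader, start=2):
            try:
                rec = VariantRecord(
                    id=int(row["id"]),
                    mutation=parse_mutation(row["mutation"]),
                    cls=row["class"].strip(),
                    subtype=row["subtype"].strip(),
                    human=row.get("human_flag", "1").strip() in ("1", "true", "True"),
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path} row {rownum}: {exc}") from exc
            records.append(rec)
    ids = [r.id for r in records]
    if sorted(ids) != list(range(len(records))):
        raise ValueError(f"{path}: ids must be unique and contiguous from 0")
    records.sort(key=lambda r: r.id)
    seen_neutral = False
    for r in records:
        if r.cls == "NEUTRAL":
            seen_neutral = True
        elif seen_neutral:
            raise ValueError(f"{path}: PAT id {r.id} appears after a NEUTRAL record")
    return records


@dataclass
class FrequencyProfile:
    """Per-position node frequency in [0, 1] for a named variant group."""

    group: str
    frequencies: dict[int, float]
    group_size: int

    def __post_init__(self) -> None:
        for pos, f in self.frequencies.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"frequency at {pos} outside [0, 1]")

    def at(self, position: int) -> float:
        return self.frequencies.get(position, 0.0)


def node_frequency(rins: dict[int, RIN], group_ids: list[int], group: str = "") -> FrequencyProfile:
    """Fraction of the group's RINs in which each residue position is a node."""
    if not group_ids:
        raise ValueError("group must be non-empty")
    counts: dict[int, int] = {}
    for gid in group_ids:
        for pos in set(rins[gid].positions()):
            counts[pos] = counts.get(pos, 0) + 1
    n = len(group_ids)
    return FrequencyProfile(
        group=group, frequencies={p: c / n for p, c in sorted(counts.items())}, group_size=n
    )


@dataclass(frozen=True)
class DivergentInterval:
    start: int
    end: int
    deviating_group: str  # group with the lower mean frequency on the run
    max_delta: float


def frequency_contrast(
    profile_a: FrequencyProfile,
    profile_b: FrequencyProfile,
    delta_threshold: float = 0.2,
) -> list[DivergentInterval]:
    """Maximal runs of consecutive positions where |freq_a - freq_b| >= threshold.

    Positions absent from both profiles are skipped; the reported deviating
    group is the one with the lower mean frequency over the run (the group
    that lost contacts there).  Intervals are disjoint and sorted.
    """
    positions = sorted(set(profile_a.frequencies) | set(profile_b.frequencies))
    flagged = [
        p
        for p in positions
        if (d := abs(profile_a.at(p) - profile_b.at(p))) >= delta_threshold and d > 0
    ]
    intervals: list[DivergentInterval] = []
    run: list[int] = []

    def close_run() -> None:
        if not run:
            return
        mean_a = float(np.mean([profile_a.at(p) for p in run]))
        mean_b = float(np.mean([profile_b.at(p) for p in run]))
        deviating = (profile_a.group or "a") if mean_a < mean_b else (profile_b.group or "b")
        max_delta = max(abs(profile_a.at(p) - profile_b.at(p)) for p in run)
        intervals.append(DivergentInterval(run[0], run[-1], deviating, max_delta))

    for p in flagged:
        if run and p == run[-1] + 1:
            run.append(p)
        else:
            close_run()
            run = [p]
    close_run()
    return intervals
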