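"""Protein structure I/O and backbone geometry.

Reads PDB files into a lightweight chain/residue/atom model, parses point
mutation strings (e.g. ``I136V``), computes backbone phi/psi dihedrals and
classifies them against a Ramachandran region map.

Only the first MODEL of a PDB file is read; alternate locations are resolved
to the highest-occupancy conformer so that parsing is deterministic.
Residue positions are kept exactly as deposited (1-based author numbering)
and are never re-indexed, so mutation positions always refer to the wild-type
sequence numbering.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "MutationSpec",
    "DihedralPair",
    "RamachandranRegion",
    "read_pdb",
    "parse_mutation",
    "compute_phi_psi",
    "classify_ramachandran",
    "default_region_map",
    "load_region_map",
    "THREE_TO_ONE",
    "ONE_TO_THREE",
    "AMINO_ACIDS",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_BACKBONE = ("N", "CA", "C")


@dataclass(frozen=True)
class Atom:
    """A heavy atom with Cartesian coordinates in Angstrom."""

    name: str
    element: str
    coord: np.ndarray
    altloc: str = ""
    occupancy: float | None = 1.0

    def __post_init__(self) -> None:
        coord = np.asarray(self.coord, dtype=float)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        object.__setattr__(self, "coord", coord)
        if self.occupancy is not None and not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    """One residue: three-letter name, chain, deposited sequence position, atoms."""

    name: str
    chain: str
    position: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.position, self.icode)

    @property
    def label(self) -> str:
        """Node identity used by the interaction-network analyses."""
        return f"{self.chain}:{self.position}{self.icode}"

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def is_complete(self) -> bool:
        """Backbone atoms N, CA, C all present."""
        return all(self.atom(n) is not None for n in _BACKBONE)


@dataclass
class Structure:
    """Ordered chains of residues parsed from a single structure file."""

    id: str
    residues: list[Residue]
    source: str = ""

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise ValueError(f"structure {self.id}: duplicate residue keys")

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def chains(self) -> dict[str, list[Residue]]:
        out: dict[str, list[Residue]] = {}
        for r in self.residues:
            out.setdefault(r.chain, []).append(r)
        return out


@dataclass(frozen=True)
class MutationSpec:
    """A point substitution in wild-type numbering, e.g. I136V."""

    wt: str
    position: int
    mut: str

    def __post_init__(self) -> None:
        if self.wt not in AMINO_ACIDS or self.mut not in AMINO_ACIDS:
            raise ValueError(f"mutation {self}: letters must be standard amino acids")
        if self.position < 1:
            raise ValueError(f"mutation {self}: position must be >= 1")
        if self.wt == self.mut:
            raise ValueError(f"mutation {self}: wild type equals mutant")

    def __str__(self) -> str:
        return f"{self.wt}{self.position}{self.mut}"


_MUTATION_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


def parse_mutation(text: str) -> MutationSpec:
    """Parse a mutation string like ``I136V`` into a :class:`MutationSpec`."""
    m = _MUTATION_RE.match(text.strip())
    if m is None:
        raise ValueError(f"cannot parse mutation string {text!r}: expected <AA><digits><AA>")
    return MutationSpec(m.group(1).upper(), int(m.group(2)), m.group(3).upper())


def read_pdb(path: str | Path, keep_hetatm: bool = False) -> Structure:
    """Read the first MODEL of a PDB file.

    Alternate locations are resolved to the highest-occupancy atom; HETATM
    records are skipped unless ``keep_hetatm`` is set.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bio = parser.get_structure(path.stem, str(path))
    except PDBConstructionException as exc:  # pragma: no cover - parser detail
        raise ValueError(f"malformed PDB record in {path}: {exc}") from exc

    models = list(bio.get_models())
    if not models:
        raise ValueError(f"{path}: no ATOM records found")
    model = models[0]

    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            hetflag, seqpos, icode = res.get_id()
            if hetflag.strip() and not keep_hetatm:
                continue
            atoms: dict[str, Atom] = {}
            for atom in res.get_unpacked_list():
                occ = atom.get_occupancy()
                cand = Atom(
                    name=atom.get_name(),
                    element=(atom.element or "").strip() or atom.get_name()[0],
                    coord=np.array(atom.get_coord(), dtype=float),
                    altloc=atom.get_altloc().strip(),
                    occupancy=None if occ is None else min(max(float(occ), 0.0), 1.0),
                )
                prev = atoms.get(cand.name)
                if prev is None or (cand.occupancy or 0.0) > (prev.occupancy or 0.0):
                    atoms[cand.name] = cand
            if atoms:
                residues.append(
                    Residue(
                        name=res.get_resname().strip(),
                        chain=chain.id,
                        position=int(seqpos),
                        icode=icode.strip(),
                        atoms=list(atoms.values()),
                    )
                )
    if not residues:
        raise ValueError(f"{path}: structure is empty (no ATOM records)")
    return Structure(id=path.stem, residues=residues, source=str(path))


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed torsion angle (degrees, in (-180, 180]) of four points."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang <= -180.0 else ang


@dataclass(frozen=True)
class DihedralPair:
    """Backbone phi/psi torsions for one residue; None where undefined."""

    key: tuple[str, int, str]
    phi: float | None
    psi: float | None


def compute_phi_psi(structure: Structure) -> list[DihedralPair]:
    """Backbone phi/psi per residue.

    phi(i) uses C(i-1), N(i), CA(i), C(i); psi(i) uses N(i), CA(i), C(i),
    N(i+1). A torsion is undefined (None) at chain termini and wherever a
    needed backbone atom is missing.
    """
    out: list[DihedralPair] = []
    for _, chain_res in structure.chains().items():
        for i, res in enumerate(chain_res):
            prev_res = chain_res[i - 1] if i > 0 else None
            next_res = chain_res[i + 1] if i + 1 < len(chain_res) else None
            n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
            phi = psi = None
            if prev_res is not None and all(a is not None for a in (n, ca, c)):
                c_prev = prev_res.atom("C")
                if c_prev is not None:
                    phi = dihedral(c_prev.coord, n.coord, ca.coord, c.coord)
            if next_res is not None and all(a is not None for a in (n, ca, c)):
                n_next = next_res.atom("N")
                if n_next is not None:
                    psi = dihedral(n.coord, ca.coord, c.coord, n_next.coord)
            out.append(DihedralPair(key=res.key, phi=phi, psi=psi))
    return out


@dataclass(frozen=True)
class RamachandranRegion:
    """A rectangle on the (phi, psi) torus assigned to a class."""

    phi_lo: float
    phi_hi: float
    psi_lo: float
    psi_hi: float
    cls: str

    def contains(self, phi: float, psi: float) -> bool:
        return self.phi_lo <= phi <= self.phi_hi and self.psi_lo <= psi <= self.psi_hi


# Coarse rectangular approximation of the usual favored/allowed regions
# (alpha-helical, beta-sheet and left-handed helical basins).  Rectangles are
# checked in order; the first match wins and anything unmatched is an outlier.
_DEFAULT_REGIONS: tuple[RamachandranRegion, ...] = (
    RamachandranRegion(-100, -30, -80, -5, "favored"),    # right-handed alpha
    RamachandranRegion(-170, -50, 90, 180, "favored"),    # beta
    RamachandranRegion(-170, -50, -180, -160, "favored"), # beta (wrapped psi)
    RamachandranRegion(30, 90, 0, 90, "favored"),         # left-handed alpha
    RamachandranRegion(-180, -20, -120, 40, "allowed"),
    RamachandranRegion(-180, -30, 60, 180, "allowed"),
    RamachandranRegion(-180, -30, -180, -150, "allowed"),
    RamachandranRegion(20, 110, -30, 110, "allowed"),
)


def default_region_map() -> tuple[RamachandranRegion, ...]:
    return _DEFAULT_REGIONS


def load_region_map(path: str | Path) -> tuple[RamachandranRegion, ...]:
    """Load a region map from a whitespace-separated table.

    Columns: phi_lo phi_hi psi_lo psi_hi class. Lines starting with '#' are
    comments.
    """
    regions = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"region map line {line!r}: expected 5 columns")
        regions.append(RamachandranRegion(*map(float, parts[:4]), cls=parts[4]))
    if not regions:
        raise ValueError(f"{path}: empty region map")
    return tuple(regions)


def classify_ramachandran(
    dihedrals: list[DihedralPair],
    region_map: tuple[RamachandranRegion, ...] | None = None,
) -> tuple[dict[tuple[str, int, str], str], dict[str, float]]:
    """Assign each defined (phi, psi) pair a region class.

    Returns a per-residue class mapping and the summary fractions over the
    defined pairs (pairs with an undefined torsion are excluded from the
    denominator). Classes are exhaustive: anything not in a favored/allowed
    rectangle is an outlier.
    """
    regions = region_map if region_map is not None else _DEFAULT_REGIONS
    classes: dict[tuple[str, int, str], str] = {}
    for d in dihedrals:
        if d.phi is None or d.psi is None:
            continue
        cls = "outlier"
        for region in regions:
            if region.contains(d.phi, d.psi):
                cls = region.cls
                break
        classes[d.key] = cls
    n = len(classes)
    names = sorted({r.cls for r in regions} | {"outlier"})
    summary = {
        name: (sum(1 for c in classes.values() if c == name) / n if n else 0.0)
        for name in names
    }
    return classes, summary
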