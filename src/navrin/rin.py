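"""Residue interaction networks (RINs).

A structure is mapped to an undirected graph whose nodes are residues
(labelled chain:position) and whose edges are typed non-covalent contacts.
Construction runs in two steps: a distance prefilter proposes candidate
residue pairs (closest heavy-atom semantics), then each candidate is tested
against per-type atom-group rules and strict distance thresholds.  At most
one edge per interaction type is kept per residue pair (the closest
qualifying atom pair), and residues left without any non-covalent edge are
dropped from the graph, so node presence itself is informative.

Default thresholds (Angstrom): hydrogen bond 3.5, van der Waals slack 0.5
over the radii sum, ionic bridge 4.0, pi-pi stacking 6.5, pi-cation 5.0,
disulfide 2.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Residue, Structure

__all__ = [
    "InteractionType",
    "RINParams",
    "RIN",
    "candidate_pairs",
    "type_interactions",
    "build_rin",
    "filter_by_type",
    "write_rin_tsv",
    "read_rin_tsv",
]

log = logging.getLogger(__name__)


class InteractionType(str, Enum):
    HBOND = "HBOND"
    VDW = "VDW"
    IONIC = "IONIC"
    PIPI = "PIPI"
    PICATION = "PICATION"
    DISULFIDE = "DISULFIDE"


# Heavy-atom van der Waals radii (A).
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "SE": 1.90}

AROMATIC_RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}

CATION_ATOMS = {
    "LYS": ("NZ",),
    "ARG": ("NH1", "NH2", "NE"),
    "HIS": ("ND1", "NE2"),
}

ANION_ATOMS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)


@dataclass(frozen=True)
class RINParams:
    """Construction parameters; defaults follow strict-threshold contact typing."""

    hbond: float = 3.5
    vdw_slack: float = 0.5
    ionic: float = 4.0
    pipi: float = 6.5
    pication: float = 5.0
    disulfide: float = 2.5
    min_separation: int = 2
    prefilter: float = 7.0
    prefilter_aromatic: float = 7.5
    vdw_radii: dict = field(default_factory=lambda: dict(VDW_RADII))

    def __post_init__(self) -> None:
        for name in ("hbond", "vdw_slack", "ionic", "pipi", "pication", "disulfide",
                     "prefilter", "prefilter_aromatic"):
            if getattr(self, name) <= 0:
                raise ValueError(f"RINParams.{name} must be positive")

    def threshold(self, kind: InteractionType) -> float:
        return {
            InteractionType.HBOND: self.hbond,
            InteractionType.IONIC: self.ionic,
            InteractionType.PIPI: self.pipi,
            InteractionType.PICATION: self.pication,
            InteractionType.DISULFIDE: self.disulfide,
        }.get(kind, self.vdw_slack)


class RIN:
    """Typed residue interaction network backed by a networkx MultiGraph.

    Edge keys are interaction type names; each edge stores the measured
    distance in Angstrom.  Nodes are string labels ``chain:position``.
    """

    def __init__(self, graph_id: str, graph: nx.MultiGraph | None = None):
        self.id = graph_id
        self.graph = graph if graph is not None else nx.MultiGraph()

    def add_edge(self, a: str, b: str, kind: InteractionType, distance: float) -> None:
        if a == b:
            raise ValueError("self-loops are not allowed in a RIN")
        self.graph.add_edge(a, b, key=kind.value, distance=float(distance))

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, str, float]]:
        out = []
        for a, b, key, data in self.graph.edges(keys=True, data=True):
            x, y = sorted((a, b))
            out.append((x, y, key, data["distance"]))
        return sorted(out)

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RIN):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def positions(self) -> list[int]:
        """Residue sequence positions of the nodes (wild-type numbering)."""
        return sorted(int(label.split(":")[1]) for label in self.graph.nodes)

    def as_labeled_graph(self) -> nx.Graph:
        """Collapse edge types into a simple graph with position node labels."""
        g = nx.Graph()
        for label in self.graph.nodes:
            g.add_node(label, label=int(label.split(":")[1]))
        g.add_edges_from({tuple(sorted((a, b))) for a, b in self.graph.edges()})
        return g


def _heavy_atoms(res: Residue) -> list:
    return [a for a in res.atoms if a.element.upper() not in ("H", "D")]


def candidate_pairs(
    structure: Structure, params: RINParams | None = None
) -> list[tuple[Residue, Residue]]:
    """Distance prefilter: residue pairs eligible for an interaction.

    A pair qualifies when the closest heavy-atom distance is within the
    prefilter radius (the aromatic radius when both residues carry an
    aromatic ring) and, within a chain, the sequence separation is at least
    ``min_separation`` (covalent neighbours are never candidates).
    """
    params = params or RINParams()
    if len(structure) == 0:
        raise ValueError("empty structure")
    residues = structure.residues
    coords, owner = [], []
    for idx, res in enumerate(residues):
        for atom in _heavy_atoms(res):
            coords.append(atom.coord)
            owner.append(idx)
    coords = np.asarray(coords)
    owner = np.asarray(owner)
    radius = max(params.prefilter, params.prefilter_aromatic)
    tree = cKDTree(coords)
    close = tree.query_pairs(radius, output_type="ndarray")

    best: dict[tuple[int, int], float] = {}
    dists = np.linalg.norm(coords[close[:, 0]] - coords[close[:, 1]], axis=1)
    for (ai, bi), d in zip(close, dists):
        i, j = owner[ai], owner[bi]
        if i == j:
            continue
        key = (min(i, j), max(i, j))
        if d < best.get(key, np.inf):
            best[key] = d

    pairs = []
    for (i, j), d in sorted(best.items()):
        ri, rj = residues[i], residues[j]
        if ri.chain == rj.chain and abs(ri.position - rj.position) < params.min_separation:
            continue
        both_aromatic = ri.name in AROMATIC_RING_ATOMS and rj.name in AROMATIC_RING_ATOMS
        limit = params.prefilter_aromatic if both_aromatic else params.prefilter
        if d <= limit:
            pairs.append((ri, rj))
    return pairs


def _closest(atoms_a, atoms_b) -> tuple[float, str, str]:
    best = (np.inf, "", "")
    for a in atoms_a:
        for b in atoms_b:
            d = float(np.linalg.norm(a.coord - b.coord))
            if d < best[0]:
                best = (d, a.name, b.name)
    return best


def _ring_centroid(res: Residue) -> np.ndarray | None:
    names = AROMATIC_RING_ATOMS.get(res.name)
    if names is None:
        return None
    coords = [res.atom(n).coord for n in names if res.atom(n) is not None]
    if len(coords) < 3:
        return None
    return np.mean(coords, axis=0)


def _detect(ri: Residue, rj: Residue, params: RINParams) -> list[tuple[InteractionType, float]]:
    """All interaction types the pair qualifies for, with measured distances."""
    found: list[tuple[InteractionType, float]] = []

    heavy_i, heavy_j = _heavy_atoms(ri), _heavy_atoms(rj)

    # Hydrogen bond: closest N/O...N/O heavy-atom pair.
    no_i = [a for a in heavy_i if a.element.upper() in ("N", "O")]
    no_j = [a for a in heavy_j if a.element.upper() in ("N", "O")]
    if no_i and no_j:
        d, _, _ = _closest(no_i, no_j)
        if d <= params.hbond:
            found.append((InteractionType.HBOND, d))

    # Van der Waals: closest heavy-atom pair within radii sum + slack.
    best_vdw = np.inf
    for a in heavy_i:
        ra = params.vdw_radii.get(a.element.upper())
        if ra is None:
            continue
        for b in heavy_j:
            rb = params.vdw_radii.get(b.element.upper())
            if rb is None:
                continue
            d = float(np.linalg.norm(a.coord - b.coord))
            if d <= ra + rb + params.vdw_slack and d < best_vdw:
                best_vdw = d
    if np.isfinite(best_vdw):
        found.append((InteractionType.VDW, best_vdw))

    # Ionic bridge: basic group atom vs acidic group atom.
    for rc, ra in ((ri, rj), (rj, ri)):
        cat = [rc.atom(n) for n in CATION_ATOMS.get(rc.name, ())]
        ani = [ra.atom(n) for n in ANION_ATOMS.get(ra.name, ())]
        cat = [a for a in cat if a is not None]
        ani = [a for a in ani if a is not None]
        if cat and ani:
            d, _, _ = _closest(cat, ani)
            if d <= params.ionic:
                found.append((InteractionType.IONIC, d))
                break

    # Pi-pi stacking: ring centroid to ring centroid.
    ci, cj = _ring_centroid(ri), _ring_centroid(rj)
    if ci is not None and cj is not None:
        d = float(np.linalg.norm(ci - cj))
        if d <= params.pipi:
            found.append((InteractionType.PIPI, d))

    # Pi-cation: ring centroid of one vs cationic atom of the other.
    best_pc = np.inf
    for ring_res, cat_res in ((ri, rj), (rj, ri)):
        centroid = _ring_centroid(ring_res)
        if centroid is None:
            continue
        for name in CATION_ATOMS.get(cat_res.name, ()):
            atom = cat_res.atom(name)
            if atom is not None:
                d = float(np.linalg.norm(centroid - atom.coord))
                best_pc = min(best_pc, d)
    if best_pc <= params.pication:
        found.append((InteractionType.PICATION, best_pc))

    # Disulfide bridge: cysteine SG pairs.
    if ri.name == "CYS" and rj.name == "CYS":
        sa, sb = ri.atom("SG"), rj.atom("SG")
        if sa is not None and sb is not None:
            d = float(np.linalg.norm(sa.coord - sb.coord))
            if d <= params.disulfide:
                found.append((InteractionType.DISULFIDE, d))

    return found


def type_interactions(
    structure: Structure,
    pairs: list[tuple[Residue, Residue]],
    params: RINParams | None = None,
    graph_id: str | None = None,
) -> RIN:
    """Type each candidate pair; emit at most one edge per type per pair.

    Residues of non-standard type are treated as interaction-inert (logged).
    Residues that end up with no edge do not appear in the graph.
    """
    params = params or RINParams()
    rin = RIN(graph_id or structure.id)
    for ri, rj in pairs:
        if ri.name not in STANDARD_RESIDUES or rj.name not in STANDARD_RESIDUES:
            log.debug("non-standard residue pair %s-%s treated as inert", ri.name, rj.name)
            continue
        for kind, dist in _detect(ri, rj, params):
            rin.add_edge(ri.label, rj.label, kind, dist)
    return rin


def build_rin(structure: Structure, params: RINParams | None = None) -> RIN:
    """Two-step RIN construction: distance prefilter, then interaction typing."""
    params = params or RINParams()
    return type_interactions(structure, candidate_pairs(structure, params), params)


def filter_by_type(rin: RIN, kind: InteractionType) -> RIN:
    """Subgraph of edges of one interaction type; isolated nodes dropped."""
    out = RIN(f"{rin.id}:{kind.value}")
    for a, b, key, dist in rin.edges:
        if key == kind.value:
            out.add_edge(a, b, InteractionType(key), dist)
    return out


def write_rin_tsv(rin: RIN, edge_path: str | Path, node_path: str | Path | None = None) -> None:
    lines = ["node_a\tnode_b\ttype\tdistance"]
    lines += [f"{a}\t{b}\t{k}\t{d:.4f}" for a, b, k, d in rin.edges]
    Path(edge_path).write_text("\n".join(lines) + "\n")
    if node_path is not None:
        Path(node_path).write_text("\n".join(["node"] + rin.nodes) + "\n")


def read_rin_tsv(edge_path: str | Path, graph_id: str | None = None) -> RIN:
    path = Path(edge_path)
    rin = RIN(graph_id or path.stem)
    lines = path.read_text().splitlines()
    header = lines[0].split("\t")
    if header[:4] != ["node_a", "node_b", "type", "distance"]:
        raise ValueError(f"{path}: unexpected edge-list header {header}")
    for line in lines[1:]:
        if not line.strip():
            continue
        a, b, kind, dist = line.split("\t")[:4]
        rin.add_edge(a, b, InteractionType(kind), float(dist))
    return rin
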