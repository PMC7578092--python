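"""Seeded generators for every synthetic input the pipeline consumes.

* poly-alanine helix PDB files built from ideal internal coordinates at
  chosen backbone torsions (NeRF chain extension);
* variant structure ensembles with planted group structure: pathogenic
  copies share a contact signature realized by a compacted "sensor segment"
  of side-chain proxy residues, neutral copies receive coordinate jitter
  only, so the two groups differ by which residues form non-covalent
  contacts;
* alignments Gibbs-sampled from a known Potts model, returned together with
  the planted interaction edges for recovery tests.

All generators are pure functions of their spec and seed.  The ensembles
emulate the *shape* of the real problem (85 variants, 31/54 class split,
typed contact graphs) but not homology-model physics: signature edges are
planted geometrically, not produced by a forcefield.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .structure_io import Structure, read_pdb
from .variant_analysis import VariantRecord, load_catalogue

__all__ = [
    "FixtureSpec",
    "PottsSpec",
    "make_helix_pdb",
    "make_variant_ensemble",
    "sample_potts_msa",
    "potts_msa_to_letters",
]

# ideal backbone internal coordinates (lengths A, angles degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
_A_C_N_CA, _A_N_CA_C, _A_CA_C_N, _A_CA_C_O, _A_C_CA_CB = 121.7, 111.2, 116.2, 120.5, 110.5
_OMEGA = 180.0


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray, r: float, theta: float, chi: float) -> np.ndarray:
    """NeRF: position atom D with bond length r (C-D), angle theta (B-C-D)
    and torsion chi (A-B-C-D), all in Angstrom/degrees."""
    theta, chi = math.radians(theta), math.radians(-chi)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-r * math.cos(theta), r * math.sin(theta) * math.cos(chi), r * math.sin(theta) * math.sin(chi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _backbone(n_residues: int, phi: float, psi: float, with_cb: bool = True) -> list[dict[str, np.ndarray]]:
    """Ideal-geometry poly-alanine backbone at constant (phi, psi)."""
    residues: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    # place C0 at the ideal N-CA-C angle; the auxiliary point fixes the frame
    c0 = _place(np.array([0.0, -1.0, 0.0]), n0, ca0, _B_CA_C, _A_N_CA_C, 60.0)
    residues.append({"N": n0, "CA": ca0, "C": c0})
    for _ in range(1, n_residues):
        prev = residues[-1]
        n_new = _place(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi)
        ca_new = _place(prev["CA"], prev["C"], n_new, _B_N_CA, _A_C_N_CA, _OMEGA)
        c_new = _place(prev["C"], n_new, ca_new, _B_CA_C, _A_N_CA_C, phi)
        residues.append({"N": n_new, "CA": ca_new, "C": c_new})
    # carbonyl O and side-chain proxy CB from completed neighbours
    for i, res in enumerate(residues):
        if i + 1 < len(residues):
            res["O"] = _place(res["N"], res["CA"], res["C"], _B_C_O, _A_CA_C_O, psi + 180.0)
        else:
            res["O"] = _place(res["N"], res["CA"], res["C"], _B_C_O, _A_CA_C_O, psi + 180.0)
        if with_cb:
            res["CB"] = _place(res["C"], res["N"], res["CA"], _B_CA_CB, _A_C_CA_CB, 240.0)
    return residues


_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}
_ATOM_ORDER = ("N", "CA", "C", "O", "CB")


def _pdb_text(residues: list[dict[str, np.ndarray]], chain: str = "A", resname: str = "ALA",
              start: int = 1) -> str:
    lines = []
    serial = 1
    for i, atoms in enumerate(residues):
        pos = start + i
        for name in _ATOM_ORDER:
            if name not in atoms:
                continue
            x, y, z = atoms[name]
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s}{resname:>4s} {chain}{pos:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {_ELEMENTS[name]:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_helix_pdb(
    n_residues: int,
    phi: float = -57.0,
    psi: float = -47.0,
    seed: int = 0,
    path: str | Path | None = None,
    jitter: float = 0.0,
) -> str:
    """Ideal poly-alanine PDB at constant backbone torsions.

    Deterministic for a fixed (spec, seed); optional Gaussian coordinate
    jitter (A) uses the seed.  Returns the PDB text; writes it when ``path``
    is given.
    """
    if n_residues < 4:
        raise ValueError("need at least 4 residues")
    for name, val in (("phi", phi), ("psi", psi)):
        if not -180.0 <= val <= 180.0:
            raise ValueError(f"{name} must be in [-180, 180]")
    residues = _backbone(n_residues, phi, psi)
    if jitter > 0:
        rng = np.random.default_rng(seed)
        for res in residues:
            for name in res:
                res[name] = res[name] + rng.normal(0.0, jitter, 3)
    text = _pdb_text(residues)
    if path is not None:
        Path(path).write_text(text)
    return text


@dataclass(frozen=True)
class FixtureSpec:
    """Conditions for the planted variant-structure ensemble.

    ``rewiring_rate`` is the probability that each sensor residue of a
    pathogenic variant adopts the compact (contact-forming) arrangement;
    at 0 the two groups are indistinguishable up to jitter.
    """

    seed: int
    n_core_residues: int = 40
    n_sensor_residues: int = 8
    rewiring_rate: float = 1.0
    jitter: float = 0.05
    sensor_spacing_compact: float = 1.6
    sensor_spacing_spread: float = 25.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rewiring_rate <= 1.0:
            raise ValueError("rewiring_rate must be in [0, 1]")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")


def _sensor_block(n: int, spacing: float, origin: np.ndarray) -> list[dict[str, np.ndarray]]:
    """A line of residues ``spacing`` A apart, each an ideal-geometry monomer."""
    template = _backbone(4, -57.0, -47.0)[1]  # one interior residue
    center = np.mean(list(template.values()), axis=0)
    out = []
    for i in range(n):
        shift = origin + np.array([0.0, 0.0, i * spacing]) - center
        out.append({name: coord + shift for name, coord in template.items()})
    return out


def make_variant_ensemble(
    spec: FixtureSpec, out_dir: str | Path | None = None
) -> tuple[dict[int, Structure], list[VariantRecord]]:
    """Build the 85-variant structure ensemble with planted group structure.

    Every structure shares a helical core; a trailing sensor segment is
    compacted (mutual side-chain contacts) in pathogenic variants at the
    rewiring rate and dispersed beyond contact range otherwise.  Returns
    structures keyed by variant id plus the catalogue records (the packaged
    85-variant catalogue, 31 pathogenic / 54 neutral).
    """
    catalogue = load_catalogue()
    rng = np.random.default_rng(spec.seed)
    core = _backbone(spec.n_core_residues, -57.0, -47.0)
    core_end = core[-1]["C"]
    sensor_origin = core_end + np.array([30.0, 0.0, 0.0])

    structures: dict[int, Structure] = {}
    tmp_dir = Path(out_dir) if out_dir is not None else None
    if tmp_dir is not None:
        tmp_dir.mkdir(parents=True, exist_ok=True)
    import tempfile

    for rec in catalogue:
        compact = rec.cls == "PAT" and (rng.random() < spec.rewiring_rate)
        if compact:
            sensors = _sensor_block(spec.n_sensor_residues, spec.sensor_spacing_compact, sensor_origin)
        else:
            sensors = _sensor_block(spec.n_sensor_residues, spec.sensor_spacing_spread, sensor_origin)
        residues = [dict(r) for r in core] + sensors
        for res in residues:
            for name in list(res):
                res[name] = res[name] + rng.normal(0.0, spec.jitter, 3)
        text = _pdb_text(residues)
        if tmp_dir is not None:
            pdb_path = tmp_dir / f"variant_{rec.id:02d}.pdb"
            pdb_path.write_text(text)
            structures[rec.id] = read_pdb(pdb_path)
        else:
            with tempfile.NamedTemporaryFile("w", suffix=".pdb", delete=False) as fh:
                fh.write(text)
                name = fh.name
            structures[rec.id] = read_pdb(name)
            Path(name).unlink()
        structures[rec.id].id = f"variant_{rec.id:02d}"
    return structures, catalogue


@dataclass(frozen=True)
class PottsSpec:
    """A planted Potts model: L sites, q states, explicit interaction edges."""

    L: int = 12
    q: int = 4
    n_edges: int = 8
    coupling_strength: float = 1.2
    field_strength: float = 0.0
    conserved_fraction: float = 0.0
    conserved_field: float = 3.0

    def __post_init__(self) -> None:
        if self.L > 50 or self.q > 8:
            raise ValueError("desk scale only: L <= 50, q <= 8")
        if not 0.0 <= self.conserved_fraction <= 1.0:
            raise ValueError("conserved_fraction must be in [0, 1]")


def _planted_model(spec: PottsSpec, rng: np.random.Generator):
    """Draw edges and parameters: ferromagnetic-style couplings on the
    planted edges, optional random fields, optional strongly conserved
    columns (large field on one state)."""
    L, q = spec.L, spec.q
    all_pairs = [(i, j) for i in range(L) for j in range(i + 1, L)]
    idx = rng.choice(len(all_pairs), size=spec.n_edges, replace=False)
    edges = sorted(all_pairs[i] for i in idx)
    J = np.zeros((L, L, q, q))
    for i, j in edges:
        Jij = spec.coupling_strength * (2.0 * np.eye(q) - 1.0)
        # random state permutation so the preferred pairing differs per edge
        perm = rng.permutation(q)
        Jij = Jij[perm][:, rng.permutation(q)]
        J[i, j] = Jij
        J[j, i] = Jij.T
    h = rng.normal(0.0, spec.field_strength, size=(L, q)) if spec.field_strength > 0 else np.zeros((L, q))
    n_cons = int(round(spec.conserved_fraction * L))
    conserved = list(rng.choice(L, size=n_cons, replace=False)) if n_cons else []
    for c in conserved:
        h[c] = -spec.conserved_field
        h[c, rng.integers(q)] = spec.conserved_field
    return h, J, edges, conserved


def sample_potts_msa(
    spec: PottsSpec,
    n_sequences: int = 2000,
    burn_in: int = 300,
    seed: int = 0,
) -> tuple[np.ndarray, list[tuple[int, int]], np.ndarray, np.ndarray]:
    """Gibbs-sample sequences from a planted Potts model.

    Runs ``n_sequences`` independent chains for ``burn_in`` full sweeps and
    keeps the final state of each.  Returns (X, edges, h, J): the integer
    (N, L) alignment, the planted edge list and the true parameters.
    """
    rng = np.random.default_rng(seed)
    h, J, edges, _ = _planted_model(spec, rng)
    L, q = spec.L, spec.q
    N = n_sequences
    X = rng.integers(0, q, size=(N, L))
    for _ in range(burn_in):
        for r in range(L):
            logits = np.broadcast_to(h[r], (N, q)).copy()
            for j in range(L):
                if j == r:
                    continue
                logits += J[r, j][:, X[:, j]].T
            gumbel = -np.log(-np.log(rng.random((N, q))))
            X[:, r] = np.argmax(logits + gumbel, axis=1)
    return X, edges, h, J


def potts_msa_to_letters(X: np.ndarray, alphabet: str = "ACDEFGHIKLMNPQRSTVWY") -> list[str]:
    """Map integer states to amino-acid letters for file export."""
    if X.max() >= len(alphabet):
        raise ValueError("alphabet too small for state count")
    lut = np.array(list(alphabet))
    return ["".join(row) for row in lut[X]]
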