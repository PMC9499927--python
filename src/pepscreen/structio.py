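"""Structure, pose-set and ensemble I/O on fixed-column PDB, plus atom annotation.

The multi-model PDB dialect doubles as both the trajectory/ensemble format and
the docking pose-set format (one MODEL per pose, score carried on a REMARK
line). Coordinates are Angstrom throughout; residue numbering follows the file.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Ensemble",
    "Pose",
    "PDBFormatError",
    "VDW_RADII",
    "COVALENT_RADII",
    "read_structure",
    "read_ensemble",
    "write_structure",
    "write_ensemble",
    "read_pose_set",
    "annotate",
    "infer_element",
]


class PDBFormatError(ValueError):
    """Raised for malformed or unusable PDB input."""


# Bondi-style van der Waals radii (Angstrom); overridable via `annotate`.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
    "B": 1.92,
}

# Covalent radii (Angstrom) used only for distance-based bond inference.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "S": 1.05,
    "P": 1.07,
    "F": 0.57,
    "CL": 1.02,
    "BR": 1.20,
    "I": 1.39,
    "SE": 1.20,
    "B": 0.84,
}

# two-letter symbols safe to infer from bare atom names; deliberately excludes
# CA/NA/CO/... which collide with standard protein atom names (use the element
# column for those)
_TWO_LETTER_ELEMENTS = {"CL", "BR", "SE", "FE", "ZN", "MG", "MN"}


@dataclass(eq=False)
class Atom:
    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    insertion_code: str
    chain_id: str
    position: np.ndarray
    vdw_radius: float | None = None
    is_polar: bool | None = None
    is_hydrogen: bool = False
    altloc: str = ""
    occupancy: float = 1.0
    hetatm: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial} {self.name}: position must be a finite 3-vector")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.insertion_code)


@dataclass
class Structure:
    """Ordered atom records for one model."""

    atoms: list[Atom]
    label: str = ""
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(f"coordinate array shape {coords.shape} does not match {len(self.atoms)} atoms")
        atoms = [replace(a, position=c.copy()) for a, c in zip(self.atoms, coords)]
        return Structure(atoms=atoms, label=self.label, provenance=self.provenance)

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def select_chains(self, chain_ids: Iterable[str]) -> "Structure":
        wanted = set(chain_ids)
        return Structure([a for a in self.atoms if a.chain_id in wanted], label=self.label)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def residues(self, chain_id: str | None = None) -> list[tuple[tuple[str, int, str], list[Atom]]]:
        """Residues in file order as (key, atoms) pairs."""
        out: dict[tuple[str, int, str], list[Atom]] = {}
        for a in self.atoms:
            if chain_id is not None and a.chain_id != chain_id:
                continue
            out.setdefault(a.residue_key, []).append(a)
        return list(out.items())


@dataclass
class Ensemble:
    """Ordered coordinate frames sharing one atom topology."""

    topology: Structure
    frames: list[np.ndarray]
    frame_interval: float = 1.0  # ps per frame
    label: str = ""

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        n = len(self.topology.atoms)
        clean = []
        for i, f in enumerate(self.frames):
            f = np.asarray(f, dtype=float)
            if f.shape != (n, 3):
                raise ValueError(f"frame {i} has shape {f.shape}, expected ({n}, 3)")
            clean.append(f)
        self.frames = clean

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def duration(self) -> float:
        """Total spanned time in ps (frame i sits at time (i+1)*frame_interval)."""
        return self.n_frames * self.frame_interval

    def frame_structure(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i])


@dataclass
class Pose:
    """One docked ligand conformation with its score."""

    ligand: Structure
    score: float
    rank: int
    compound_id: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError(f"pose rank {self.rank}: score must be finite")
        if self.rank < 1:
            raise ValueError("rank must be >= 1")


# ---------------------------------------------------------------------------
# element / annotation helpers
# ---------------------------------------------------------------------------

def infer_element(atom_name: str, element_field: str = "") -> str:
    """Resolve an element symbol from the element column or the atom name."""
    el = element_field.strip().upper()
    if el:
        return el
    name = atom_name.strip()
    # names like "1HB2" / "2HG" are hydrogens
    stripped = name.lstrip("0123456789")
    if not stripped:
        raise PDBFormatError(f"cannot infer element from atom name {atom_name!r}")
    if stripped[0] == "H":
        return "H"
    two = stripped[:2].upper()
    if two in _TWO_LETTER_ELEMENTS:
        return two
    return stripped[0].upper()


def _bond_pairs(atoms: Sequence[Atom], tolerance: float = 0.45) -> list[tuple[int, int]]:
    """Distance-based covalent bond inference."""
    from scipy.spatial import cKDTree

    if not atoms:
        return []
    coords = np.array([a.position for a in atoms])
    radii = np.array([COVALENT_RADII.get(a.element, 0.77) for a in atoms])
    tree = cKDTree(coords)
    rmax = 2 * radii.max() + tolerance
    pairs = []
    for i, j in tree.query_pairs(rmax):
        d = np.linalg.norm(coords[i] - coords[j])
        if 0.4 < d <= radii[i] + radii[j] + tolerance:
            pairs.append((i, j))
    return pairs


def annotate(
    structure: Structure,
    radius_set: dict[str, float] | None = None,
    polarity_rules: dict[str, bool] | None = None,
) -> Structure:
    """Assign element, vdW radius and polarity to every atom (idempotent).

    Polar atoms: N, O, S bearing a bonded hydrogen (thiol), and hydrogens
    bonded to N/O. Bonds are inferred by distance. ``radius_set`` overrides
    the bundled element->radius table; ``polarity_rules`` overrides the
    per-element polar default (keys are element symbols).
    """
    radii = dict(VDW_RADII)
    if radius_set:
        radii.update({k.upper(): v for k, v in radius_set.items()})
    atoms = []
    for a in structure.atoms:
        el = infer_element(a.name, a.element)
        if el not in radii:
            raise PDBFormatError(
                f"unknown element {el!r} for atom {a.serial} {a.name} "
                f"{a.residue_name}{a.residue_seq}: no radius available"
            )
        atoms.append(replace(a, element=el, vdw_radius=radii[el], is_hydrogen=(el == "H")))

    polar_base = {"N": True, "O": True}
    if polarity_rules:
        polar_base.update({k.upper(): v for k, v in polarity_rules.items()})

    bonds = _bond_pairs(atoms)
    neighbors: dict[int, list[int]] = {i: [] for i in range(len(atoms))}
    for i, j in bonds:
        neighbors[i].append(j)
        neighbors[j].append(i)

    for i, a in enumerate(atoms):
        if a.element in polar_base:
            a.is_polar = polar_base[a.element]
        elif a.element == "S":
            a.is_polar = any(atoms[j].element == "H" for j in neighbors[i])
        elif a.element == "H":
            a.is_polar = any(atoms[j].element in ("N", "O") for j in neighbors[i])
        else:
            a.is_polar = False
    return Structure(atoms=atoms, label=structure.label, provenance=structure.provenance)


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> Atom:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        res_name = line[17:20].strip()
        chain = line[21].strip()
        res_seq = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PDBFormatError(f"malformed ATOM/HETATM record at line {lineno}: {exc}") from exc
    return Atom(
        serial=serial,
        name=name,
        element=element,
        residue_name=res_name,
        residue_seq=res_seq,
        insertion_code=icode,
        chain_id=chain,
        position=np.array([x, y, z]),
        altloc=altloc,
        occupancy=occupancy,
        hetatm=line.startswith("HETATM"),
    )


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep the highest-occupancy altloc per atom site; ties keep the first."""
    best: dict[tuple, int] = {}
    order: list[tuple] = []
    for idx, a in enumerate(atoms):
        key = (a.chain_id, a.residue_seq, a.insertion_code, a.name)
        if key not in best:
            best[key] = idx
            order.append(key)
        elif atoms[idx].occupancy > atoms[best[key]].occupancy:
            best[key] = idx
    return [replace(atoms[best[k]], altloc="") for k in order]


def _parse_models(path: str | Path) -> list[tuple[list[Atom], list[str]]]:
    """Return (atoms, remark_lines) per model."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    models: list[tuple[list[Atom], list[str]]] = []
    current_atoms: list[Atom] = []
    current_remarks: list[str] = []
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                if in_model and (current_atoms or current_remarks):
                    models.append((current_atoms, current_remarks))
                current_atoms, current_remarks = [], []
                in_model = True
            elif rec == "ENDMDL":
                models.append((current_atoms, current_remarks))
                current_atoms, current_remarks = [], []
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                current_atoms.append(_parse_atom_line(line.rstrip("\n"), lineno))
            elif rec == "REMARK":
                current_remarks.append(line.rstrip("\n"))
    if current_atoms or (in_model and current_remarks):
        models.append((current_atoms, current_remarks))
    models = [m for m in models if m[0]]
    if not models:
        raise PDBFormatError(f"{path}: no ATOM/HETATM records found")
    return models


def read_structure(path: str | Path, model_policy: str = "first") -> list[Structure]:
    """Read PDB into one Structure per MODEL (or one when unmodelled).

    model_policy: "first" keeps only the first model, "all" keeps every model.
    """
    if model_policy not in ("first", "all"):
        raise ValueError("model_policy must be 'first' or 'all'")
    models = _parse_models(path)
    if model_policy == "first":
        models = models[:1]
    label = Path(path).stem
    out = []
    for i, (atoms, _remarks) in enumerate(models):
        out.append(
            Structure(
                atoms=_resolve_altlocs(atoms),
                label=label if len(models) == 1 else f"{label}[{i}]",
                provenance=str(path),
            )
        )
    return out


def read_ensemble(path: str | Path, frame_interval: float = 1.0, label: str = "") -> Ensemble:
    """Read a multi-model PDB as a coordinate ensemble on the first model's topology."""
    models = _parse_models(path)
    topo_atoms = _resolve_altlocs(models[0][0])
    topology = Structure(atoms=topo_atoms, label=label or Path(path).stem, provenance=str(path))
    frames = []
    n = len(topo_atoms)
    for i, (atoms, _remarks) in enumerate(models):
        atoms = _resolve_altlocs(atoms)
        if len(atoms) != n:
            raise PDBFormatError(f"{path}: model {i + 1} has {len(atoms)} atoms, expected {n}")
        frames.append(np.array([a.position for a in atoms]))
    return Ensemble(topology=topology, frames=frames, frame_interval=frame_interval, label=topology.label)


DEFAULT_SCORE_PATTERN = (
    r"REMARK\s+(?:VINA\s+RESULT:?|SMINA\s+RESULT:?|minimizedAffinity:?|SCORE:?)\s*(-?\d+(?:\.\d+)?)"
)


def read_pose_set(
    path: str | Path,
    compound_id: str = "",
    score_pattern: str = DEFAULT_SCORE_PATTERN,
) -> list[Pose]:
    """Read a multi-model pose file; poses sorted by ascending score, ranks 1..n.

    Each MODEL must carry a REMARK score line matching ``score_pattern``
    (group 1 = the score). Ties keep file order (stable sort).
    """
    models = _parse_models(path)
    pattern = re.compile(score_pattern)
    compound_id = compound_id or Path(path).stem
    scored: list[tuple[float, Structure]] = []
    for i, (atoms, remarks) in enumerate(models):
        score = None
        for line in remarks:
            m = pattern.search(line)
            if m:
                score = float(m.group(1))
                break
        if score is None:
            raise PDBFormatError(f"{path}: model {i + 1} has no score REMARK record")
        scored.append((score, Structure(atoms=_resolve_altlocs(atoms), label=f"{compound_id}[{i}]")))
    scored.sort(key=lambda t: t[0])  # stable
    return [
        Pose(ligand=s, score=sc, rank=r, compound_id=compound_id)
        for r, (sc, s) in enumerate(scored, start=1)
    ]


# ---------------------------------------------------------------------------
# PDB writing
# ---------------------------------------------------------------------------

def _format_atom(a: Atom, serial: int) -> str:
    record = "HETATM" if a.hetatm else "ATOM  "
    name = a.name
    # PDB column convention: 1-3 char names start in column 14
    if len(name) < 4 and (not a.element or len(a.element) == 1):
        name = f" {name}"
    x, y, z = a.position
    element = (a.element or "").rjust(2)[:2]
    return (
        f"{record}{serial:>5d} {name:<4.4s}{a.altloc or ' ':1.1s}{a.residue_name:>3.3s} "
        f"{a.chain_id or ' ':1.1s}{a.residue_seq:>4d}{a.insertion_code or ' ':1.1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}          {element}"
    )


def _write_model_atoms(fh, structure: Structure) -> None:
    prev_chain = None
    serial = 0
    for a in structure.atoms:
        if prev_chain is not None and a.chain_id != prev_chain:
            fh.write("TER\n")
        serial += 1
        fh.write(_format_atom(a, serial) + "\n")
        prev_chain = a.chain_id
    fh.write("TER\n")


def write_structure(structure: Structure, path: str | Path) -> None:
    if not structure.atoms:
        raise ValueError("refusing to write an empty structure")
    with open(path, "w") as fh:
        _write_model_atoms(fh, structure)
        fh.write("END\n")


def write_ensemble(
    ensemble: Ensemble,
    path: str | Path,
    remarks_per_frame: list[list[str]] | None = None,
) -> None:
    """Write an ensemble as multi-model PDB, optionally with per-frame REMARKs."""
    if ensemble.n_frames == 0:
        raise ValueError("refusing to write an empty ensemble")
    with open(path, "w") as fh:
        for i in range(ensemble.n_frames):
            fh.write(f"MODEL {i + 1:>8d}\n")
            if remarks_per_frame is not None:
                for line in remarks_per_frame[i]:
                    fh.write(line.rstrip("\n") + "\n")
            _write_model_atoms(fh, ensemble.frame_structure(i))
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_pose_set(poses: Sequence[Pose], path: str | Path) -> None:
    """Write poses as multi-model PDB with VINA-style score REMARKs."""
    if not poses:
        raise ValueError("refusing to write an empty pose set")
    with open(path, "w") as fh:
        for i, pose in enumerate(poses):
            fh.write(f"MODEL {i + 1:>8d}\n")
            fh.write(f"REMARK VINA RESULT:    {pose.score:8.3f}\n")
            _write_model_atoms(fh, pose.ligand)
            fh.write("ENDMDL\n")
        fh.write("END\n")
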