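"""Docking post-processing cascade.

Per-pose geometric triage (backbone dihedral compliance, peptide-bond
planarity / cis detection, intramolecular steric clash screening) applied to
the top-N poses of each compound, followed by a merge-and-sort across
compounds and a docking-energy cutoff. "Intramolecular contacts" is screened
as steric overlap beyond van der Waals contact, excluding atom pairs closer
than a minimum bond-path separation — literal self-contacts would reject
every folded conformation.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .geometry import backbone_torsions
from .structio import COVALENT_RADII, Pose, Structure, annotate

__all__ = [
    "RamachandranMap",
    "FilterConfig",
    "VerdictComponent",
    "PoseVerdict",
    "SelectionReport",
    "filter_ramachandran",
    "filter_peptide_bonds",
    "filter_clashes",
    "apply_energy_cut",
    "evaluate_pose",
    "run_cascade",
    "BackboneError",
]


class BackboneError(ValueError):
    """Pose ligand has no resolvable peptide backbone (distinct from a filter fail)."""


@dataclass
class FilterConfig:
    top_n_poses: int = 20
    energy_cutoff: float = -8.0  # kcal/mol; keep score <= cutoff (inclusive)
    omega_cis_max: float = 30.0  # |omega| <= this -> cis
    omega_trans_min: float = 150.0  # |omega| >= this -> trans
    clash_overlap: float = 0.4  # Angstrom of allowed vdW interpenetration
    min_bond_separation: int = 4  # pairs closer than this many bonds are exempt

    def __post_init__(self) -> None:
        if not (0 < self.omega_cis_max < self.omega_trans_min <= 180):
            raise ValueError("need 0 < omega_cis_max < omega_trans_min <= 180")
        if self.top_n_poses < 1:
            raise ValueError("top_n_poses must be >= 1")


# ---------------------------------------------------------------------------
# Ramachandran map
# ---------------------------------------------------------------------------

RAMA_CLASSES = ("general", "glycine", "proline")


class RamachandranMap:
    """Boolean allowed-region masks over a (phi, psi) grid per residue class.

    Bins tile (-180, 180]^2; masks are indexed [phi_bin, psi_bin]. The default
    map is a coarse 10-degree mask bundled as package data; substitute stricter
    masks via :meth:`from_file`.
    """

    def __init__(self, masks: dict[str, np.ndarray], bin_width: float = 10.0):
        self.bin_width = float(bin_width)
        n = int(round(360.0 / bin_width))
        if n * bin_width != 360.0:
            raise ValueError("bin_width must divide 360")
        self.n_bins = n
        self.masks: dict[str, np.ndarray] = {}
        for cls in RAMA_CLASSES:
            if cls not in masks:
                raise ValueError(f"missing mask for class {cls!r}")
            mask = np.asarray(masks[cls], dtype=bool)
            if mask.shape != (n, n):
                raise ValueError(f"mask for {cls!r} has shape {mask.shape}, expected ({n}, {n})")
            if not mask.any():
                raise ValueError(f"mask for {cls!r} allows no bins")
            self.masks[cls] = mask

    def bin_index(self, angle: float) -> int:
        """Bin of an angle in (-180, 180]; the upper edge belongs to the bin."""
        idx = int(np.ceil((angle + 180.0) / self.bin_width)) - 1
        return min(max(idx, 0), self.n_bins - 1)

    def allowed(self, phi: float, psi: float, residue_class: str) -> bool:
        mask = self.masks[residue_class]
        return bool(mask[self.bin_index(phi), self.bin_index(psi)])

    @staticmethod
    def residue_class(residue_name: str, has_cbeta: bool = True) -> str:
        name = residue_name.upper()
        if name == "GLY":
            return "glycine"
        if name == "PRO":
            return "proline"
        # non-natural residues: general unless Gly-like (no C-beta)
        return "general" if has_cbeta else "glycine"

    @classmethod
    def from_file(cls, path: str | Path) -> "RamachandranMap":
        """Load from the bundled TSV dialect: header '# bin_width: W', then one
        'class<TAB>phi_index<TAB>psi_index' line per allowed bin."""
        bin_width = 10.0
        allowed: dict[str, list[tuple[int, int]]] = {c: [] for c in RAMA_CLASSES}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    if "bin_width" in line:
                        bin_width = float(line.split(":")[1])
                    continue
                cls_name, pi, qi = line.split("\t")
                allowed[cls_name].append((int(pi), int(qi)))
        n = int(round(360.0 / bin_width))
        masks = {}
        for cls_name, bins in allowed.items():
            mask = np.zeros((n, n), dtype=bool)
            for pi, qi in bins:
                mask[pi, qi] = True
            masks[cls_name] = mask
        return cls(masks, bin_width=bin_width)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# bin_width: {self.bin_width:g}\n")
            for cls_name in RAMA_CLASSES:
                for pi, qi in zip(*np.nonzero(self.masks[cls_name])):
                    fh.write(f"{cls_name}\t{pi}\t{qi}\n")

    @classmethod
    def default(cls) -> "RamachandranMap":
        with resources.as_file(resources.files("pepscreen") / "data" / "rama_default.tsv") as p:
            return cls.from_file(p)


# Rectangles (phi_min, phi_max, psi_min, psi_max) delimiting coarse allowed
# regions; bins whose centers fall inside any rectangle are allowed.
_GENERAL_REGIONS = [
    (-180.0, -20.0, 60.0, 180.0),  # beta sheet
    (-180.0, -20.0, -180.0, -150.0),  # beta, wrapped psi tail
    (-160.0, -20.0, -120.0, 30.0),  # right-handed alpha
    (40.0, 90.0, 0.0, 70.0),  # left-handed alpha (narrow)
]
_PROLINE_REGIONS = [
    (-110.0, -40.0, -70.0, 10.0),
    (-110.0, -40.0, 100.0, 180.0),
    (-110.0, -40.0, -180.0, -150.0),
]


def build_default_map(bin_width: float = 10.0) -> RamachandranMap:
    """Construct the bundled coarse map from its region rectangles."""
    n = int(round(360.0 / bin_width))
    centers = -180.0 + bin_width * (np.arange(n) + 0.5)

    def mask_from(regions):
        mask = np.zeros((n, n), dtype=bool)
        for pmin, pmax, qmin, qmax in regions:
            pi = (centers >= pmin) & (centers <= pmax)
            qi = (centers >= qmin) & (centers <= qmax)
            mask[np.ix_(pi, qi)] = True
        return mask

    general = mask_from(_GENERAL_REGIONS)
    # glycine: general plus its inversion through the origin
    glycine = general | general[::-1, ::-1]
    proline = mask_from(_PROLINE_REGIONS)
    return RamachandranMap(
        {"general": general, "glycine": glycine, "proline": proline}, bin_width=bin_width
    )


# ---------------------------------------------------------------------------
# verdicts
# ---------------------------------------------------------------------------

@dataclass
class VerdictComponent:
    passed: bool
    failures: list = field(default_factory=list)  # per-residue / per-bond / per-pair details


@dataclass
class PoseVerdict:
    compound_id: str
    rank: int
    score: float
    ramachandran: VerdictComponent
    peptide_bonds: VerdictComponent
    clashes: VerdictComponent

    @property
    def pass_ramachandran(self) -> bool:
        return self.ramachandran.passed

    @property
    def pass_peptide_bonds(self) -> bool:
        return self.peptide_bonds.passed

    @property
    def pass_clashes(self) -> bool:
        return self.clashes.passed

    @property
    def pass_overall(self) -> bool:
        return self.pass_ramachandran and self.pass_peptide_bonds and self.pass_clashes


@dataclass
class SelectionReport:
    verdicts: list[PoseVerdict]
    survivors: list[Pose]  # merged, sorted, energy-cut applied
    per_compound_best: dict[str, float]  # best surviving score per compound
    stage_counts: dict[str, int]


# ---------------------------------------------------------------------------
# single filters
# ---------------------------------------------------------------------------

def _ligand_torsions(pose: Pose):
    structure = pose.ligand
    chains = structure.chains()
    records = []
    has_backbone = False
    for chain in chains:
        recs = backbone_torsions(structure, chain)
        for key, atoms in structure.residues(chain):
            names = {a.name for a in atoms}
            if {"N", "CA", "C"} <= names:
                has_backbone = True
        records.extend(recs)
    if not has_backbone:
        raise BackboneError(
            f"pose {pose.compound_id} rank {pose.rank}: no resolvable peptide backbone"
        )
    return records


def filter_ramachandran(pose: Pose, rama_map: RamachandranMap | None = None) -> VerdictComponent:
    """Fail iff any residue with both phi and psi defined sits in a disallowed bin.

    Undefined angles (termini, missing atoms) never fail. Raises BackboneError
    when the ligand has no peptide backbone at all.
    """
    rama_map = rama_map or RamachandranMap.default()
    records = _ligand_torsions(pose)
    cbeta = {
        key: any(a.name == "CB" for a in atoms)
        for chain in pose.ligand.chains()
        for key, atoms in pose.ligand.residues(chain)
    }
    failures = []
    for rec in records:
        if rec.phi is None or rec.psi is None:
            continue
        has_cb = cbeta.get((rec.chain_id, rec.residue_seq, ""), True)
        cls = RamachandranMap.residue_class(rec.residue_name, has_cbeta=has_cb)
        if not rama_map.allowed(rec.phi, rec.psi, cls):
            failures.append((rec.chain_id, rec.residue_seq, rec.residue_name, rec.phi, rec.psi))
    return VerdictComponent(passed=not failures, failures=failures)


def filter_peptide_bonds(pose: Pose, config: FilterConfig | None = None) -> VerdictComponent:
    """Classify each peptide bond trans / cis / non-planar by |omega|; fail on cis or non-planar."""
    config = config or FilterConfig()
    records = _ligand_torsions(pose)
    failures = []
    n_bonds = 0
    for rec in records[:-1] if records else []:
        if rec.omega is None:
            warnings.warn(
                f"pose {pose.compound_id} rank {pose.rank}: omega undefined for residue "
                f"{rec.residue_name}{rec.residue_seq}, bond skipped",
                stacklevel=2,
            )
            continue
        n_bonds += 1
        abs_omega = abs(rec.omega)
        if abs_omega >= config.omega_trans_min:
            continue  # trans
        kind = "cis" if abs_omega <= config.omega_cis_max else "non-planar"
        failures.append((rec.chain_id, rec.residue_seq, rec.residue_name, rec.omega, kind))
    return VerdictComponent(passed=not failures, failures=failures)


_BACKBONE_TEMPLATE_BONDS = {("N", "CA"), ("CA", "C"), ("C", "O"), ("CA", "CB"), ("C", "OXT")}
_TEMPLATE_NAMES = {"N", "CA", "C", "O", "CB", "OXT"}


def _bond_adjacency(atoms) -> dict[int, list[int]]:
    """Covalent topology: template bonds by atom name for the peptide backbone
    (robust to distorted geometry), distance inference for everything else."""
    coords = np.array([a.position for a in atoms])
    radii = np.array([COVALENT_RADII.get(a.element, 0.77) for a in atoms])
    adj: dict[int, list[int]] = {i: [] for i in range(len(atoms))}

    def connect(i, j):
        adj[i].append(j)
        adj[j].append(i)

    by_residue: dict[tuple, dict[str, int]] = {}
    residue_order: list[tuple] = []
    for i, a in enumerate(atoms):
        key = a.residue_key
        if key not in by_residue:
            by_residue[key] = {}
            residue_order.append(key)
        by_residue[key].setdefault(a.name, i)

    for key in residue_order:
        names = by_residue[key]
        for n1, n2 in _BACKBONE_TEMPLATE_BONDS:
            if n1 in names and n2 in names:
                connect(names[n1], names[n2])
    for prev, nxt in zip(residue_order, residue_order[1:]):
        if prev[0] == nxt[0] and "C" in by_residue[prev] and "N" in by_residue[nxt]:
            connect(by_residue[prev]["C"], by_residue[nxt]["N"])

    # non-template atoms (sidechains beyond CB, hetero groups): by distance
    loose = [i for i, a in enumerate(atoms) if a.name not in _TEMPLATE_NAMES]
    if loose:
        tree = cKDTree(coords)
        for i in loose:
            for j in tree.query_ball_point(coords[i], radii[i] + radii.max() + 0.45):
                if j == i or j in adj[i]:
                    continue
                d = np.linalg.norm(coords[i] - coords[j])
                if 0.4 < d <= radii[i] + radii[j] + 0.45:
                    connect(i, j)
    return adj


def _bond_separation_exempt(atoms, max_sep: int) -> set[tuple[int, int]]:
    """Atom index pairs connected by fewer than max_sep bonds (BFS on topology)."""
    adj = _bond_adjacency(atoms)
    exempt: set[tuple[int, int]] = set()
    for start in range(len(atoms)):
        dist = {start: 0}
        queue = deque([start])
        while queue:
            u = queue.popleft()
            if dist[u] >= max_sep - 1:
                continue
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    queue.append(v)
        for v, d in dist.items():
            if start < v:
                exempt.add((start, v))
    return exempt


def filter_clashes(pose: Pose, config: FilterConfig | None = None) -> VerdictComponent:
    """Fail iff any heavy-atom pair >= min_bond_separation bonds apart overlaps
    by more than clash_overlap beyond van der Waals contact."""
    config = config or FilterConfig()
    ligand = pose.ligand
    if any(a.vdw_radius is None for a in ligand.atoms):
        ligand = annotate(ligand)
    heavy = [a for a in ligand.atoms if not a.is_hydrogen]
    if not heavy:
        raise ValueError("pose has no heavy atoms")
    exempt = _bond_separation_exempt(heavy, config.min_bond_separation)
    coords = np.array([a.position for a in heavy])
    radii = np.array([a.vdw_radius for a in heavy])
    tree = cKDTree(coords)
    failures = []
    for i, j in sorted(tree.query_pairs(2 * radii.max() - config.clash_overlap)):
        if (i, j) in exempt:
            continue
        d = float(np.linalg.norm(coords[i] - coords[j]))
        threshold = radii[i] + radii[j] - config.clash_overlap
        if d < threshold:
            ai, aj = heavy[i], heavy[j]
            failures.append(
                (
                    f"{ai.residue_name}{ai.residue_seq}:{ai.name}",
                    f"{aj.residue_name}{aj.residue_seq}:{aj.name}",
                    d,
                    threshold,
                )
            )
    return VerdictComponent(passed=not failures, failures=failures)


def apply_energy_cut(poses: Sequence[Pose], config: FilterConfig | None = None) -> list[Pose]:
    """Keep poses with score <= energy_cutoff (inclusive); order preserved."""
    config = config or FilterConfig()
    return [p for p in poses if p.score <= config.energy_cutoff]


def evaluate_pose(
    pose: Pose, rama_map: RamachandranMap | None = None, config: FilterConfig | None = None
) -> PoseVerdict:
    rama_map = rama_map or RamachandranMap.default()
    config = config or FilterConfig()
    return PoseVerdict(
        compound_id=pose.compound_id,
        rank=pose.rank,
        score=pose.score,
        ramachandran=filter_ramachandran(pose, rama_map),
        peptide_bonds=filter_peptide_bonds(pose, config),
        clashes=filter_clashes(pose, config),
    )


def run_cascade(
    pose_library: Mapping[str, Sequence[Pose]],
    rama_map: RamachandranMap | None = None,
    config: FilterConfig | None = None,
) -> SelectionReport:
    """Full triage: per-compound top-N geometric filters, merge, sort, energy cut.

    Merged ordering is deterministic: ascending score, then compound_id, then
    rank. Stage counts trace the funnel.
    """
    if not pose_library:
        raise ValueError("empty pose library")
    rama_map = rama_map or RamachandranMap.default()
    config = config or FilterConfig()

    verdicts: list[PoseVerdict] = []
    geometric_survivors: list[Pose] = []
    counts = {
        "input_poses": sum(len(v) for v in pose_library.values()),
        "considered": 0,
        "pass_ramachandran": 0,
        "pass_peptide_bonds": 0,
        "pass_clashes": 0,
        "pass_energy": 0,
    }
    for compound_id in sorted(pose_library):
        poses = sorted(pose_library[compound_id], key=lambda p: p.rank)[: config.top_n_poses]
        counts["considered"] += len(poses)
        for pose in poses:
            verdict = evaluate_pose(pose, rama_map, config)
            verdicts.append(verdict)
            if not verdict.pass_ramachandran:
                continue
            counts["pass_ramachandran"] += 1
            if not verdict.pass_peptide_bonds:
                continue
            counts["pass_peptide_bonds"] += 1
            if not verdict.pass_clashes:
                continue
            counts["pass_clashes"] += 1
            geometric_survivors.append(pose)

    merged = sorted(geometric_survivors, key=lambda p: (p.score, p.compound_id, p.rank))
    survivors = apply_energy_cut(merged, config)
    counts["pass_energy"] = len(survivors)

    best: dict[str, float] = {}
    for p in survivors:
        if p.compound_id not in best or p.score < best[p.compound_id]:
            best[p.compound_id] = p.score
    return SelectionReport(
        verdicts=verdicts, survivors=survivors, per_compound_best=best, stage_counts=counts
    )
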