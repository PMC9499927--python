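"""Intermolecular residue contacts and cross-complex contact conservation.

A contact is a receptor/partner residue pair whose minimum heavy-atom distance
is within the cutoff (default 4.0 Angstrom, inclusive). Conservation is
tabulated by receptor residue number across complexes, with a configurable
fraction threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .geometry import superpose
from .structio import Structure

__all__ = [
    "ContactConfig",
    "ContactPair",
    "ConservationRow",
    "ConservationTable",
    "find_contacts",
    "conservation_table",
    "superpose_complexes",
]

ResidueId = tuple[str, int, str]  # chain_id, residue_seq, residue_name


@dataclass
class ContactConfig:
    cutoff: float = 4.0  # Angstrom, inclusive
    heavy_atoms_only: bool = True
    conservation_fraction: float = 0.75

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")
        if not 0 < self.conservation_fraction <= 1:
            raise ValueError("conservation_fraction must be in (0, 1]")


@dataclass
class ContactPair:
    receptor_residue: ResidueId
    partner_residue: ResidueId
    min_distance: float


@dataclass
class ConservationRow:
    receptor_seq: int
    receptor_name: str
    # per complex label: partner residues contacted there (empty = no contact)
    per_complex: dict[str, list[ResidueId]]
    n_contacted: int
    conserved: bool


@dataclass
class ConservationTable:
    rows: list[ConservationRow]
    complex_labels: list[str]
    n_complexes: int
    fraction: float

    def to_tsv(self) -> str:
        header = ["receptor_residue"] + self.complex_labels + ["n_contacted", "conserved"]
        lines = ["\t".join(header)]
        for row in self.rows:
            cells = [f"{row.receptor_name}{row.receptor_seq}"]
            for label in self.complex_labels:
                partners = row.per_complex.get(label, [])
                cells.append(
                    ",".join(f"{name}{seq}" for _, seq, name in partners) if partners else "-"
                )
            cells.append(str(row.n_contacted))
            cells.append("yes" if row.conserved else "no")
            lines.append("\t".join(cells))
        return "\n".join(lines) + "\n"

    def conserved_residues(self) -> list[tuple[int, str]]:
        return [(r.receptor_seq, r.receptor_name) for r in self.rows if r.conserved]


def _side_atoms(structure: Structure, chains: set[str], heavy_only: bool):
    atoms = [
        a
        for a in structure.atoms
        if a.chain_id in chains and not (heavy_only and (a.is_hydrogen or a.element == "H" or a.name.startswith("H")))
    ]
    return atoms


def find_contacts(
    complex_structure: Structure,
    receptor_sel: Iterable[str],
    partner_sel: Iterable[str],
    config: ContactConfig | None = None,
) -> list[ContactPair]:
    """Residue pairs across the interface with min atom distance <= cutoff."""
    config = config or ContactConfig()
    rec_chains = set(receptor_sel)
    par_chains = set(partner_sel)
    if not rec_chains or not par_chains:
        raise ValueError("receptor and partner selections must be non-empty")
    if rec_chains & par_chains:
        raise ValueError(f"selections overlap on chains {sorted(rec_chains & par_chains)}")

    rec_atoms = _side_atoms(complex_structure, rec_chains, config.heavy_atoms_only)
    par_atoms = _side_atoms(complex_structure, par_chains, config.heavy_atoms_only)
    if not rec_atoms:
        raise ValueError(f"receptor selection {sorted(rec_chains)} matched no atoms")
    if not par_atoms:
        raise ValueError(f"partner selection {sorted(par_chains)} matched no atoms")

    rec_xyz = np.array([a.position for a in rec_atoms])
    par_xyz = np.array([a.position for a in par_atoms])
    pairs = cKDTree(rec_xyz).query_ball_tree(cKDTree(par_xyz), r=config.cutoff)

    best: dict[tuple[ResidueId, ResidueId], float] = {}
    for i, hits in enumerate(pairs):
        ra = rec_atoms[i]
        rid = (ra.chain_id, ra.residue_seq, ra.residue_name)
        for j in hits:
            pa = par_atoms[j]
            d = float(np.linalg.norm(ra.position - pa.position))
            if d > config.cutoff:
                continue
            key = (rid, (pa.chain_id, pa.residue_seq, pa.residue_name))
            if key not in best or d < best[key]:
                best[key] = d
    out = [
        ContactPair(receptor_residue=r, partner_residue=p, min_distance=d)
        for (r, p), d in best.items()
    ]
    out.sort(key=lambda c: (c.receptor_residue[1], c.receptor_residue[0], c.partner_residue[1]))
    return out


def conservation_table(
    complexes: Sequence[tuple[Structure, Iterable[str], Iterable[str]]],
    config: ContactConfig | None = None,
) -> ConservationTable:
    """Tabulate which receptor residues are contacted in which complexes.

    Receptor residues correspond across complexes by residue number (shared
    reference numbering); one row per residue contacted in >= 1 complex, with
    ``conserved`` set when the contacted fraction reaches the config threshold.
    """
    config = config or ContactConfig()
    if not complexes:
        raise ValueError("need at least one complex")
    labels = []
    per_complex_contacts: dict[str, list] = {}
    for idx, (structure, rec_sel, par_sel) in enumerate(complexes):
        label = structure.label or f"complex{idx + 1}"
        if label in per_complex_contacts:
            label = f"{label}#{idx + 1}"
        labels.append(label)
        per_complex_contacts[label] = find_contacts(structure, rec_sel, par_sel, config)

    rows_map: dict[int, ConservationRow] = {}
    for label in labels:
        for pair in per_complex_contacts[label]:
            _, seq, name = pair.receptor_residue
            row = rows_map.get(seq)
            if row is None:
                row = ConservationRow(
                    receptor_seq=seq, receptor_name=name, per_complex={}, n_contacted=0, conserved=False
                )
                rows_map[seq] = row
            row.per_complex.setdefault(label, []).append(pair.partner_residue)

    n = len(complexes)
    rows = []
    for seq in sorted(rows_map):
        row = rows_map[seq]
        row.n_contacted = len(row.per_complex)
        row.conserved = row.n_contacted / n >= config.conservation_fraction
        rows.append(row)
    return ConservationTable(rows=rows, complex_labels=labels, n_complexes=n, fraction=config.conservation_fraction)


def superpose_complexes(
    complexes: Sequence[Structure],
    reference: Structure,
    receptor_sel: Iterable[str],
) -> list[tuple[Structure, float]]:
    """Bring each complex into the reference frame via shared receptor CA atoms.

    CA atoms are matched by (residue_seq, insertion_code) within the receptor
    chains; needs >= 3 matches. Returns (transformed structure, fit RMSD) pairs.
    """
    rec_chains = set(receptor_sel)

    def ca_map(s: Structure) -> dict[tuple[int, str], np.ndarray]:
        return {
            (a.residue_seq, a.insertion_code): a.position
            for a in s.atoms
            if a.chain_id in rec_chains and a.name == "CA"
        }

    ref_cas = ca_map(reference)
    out = []
    for s in complexes:
        mob_cas = ca_map(s)
        shared = sorted(set(ref_cas) & set(mob_cas))
        if len(shared) < 3:
            raise ValueError(
                f"complex {s.label!r}: only {len(shared)} matched receptor CA atoms (need >= 3)"
            )
        mobile = np.array([mob_cas[k] for k in shared])
        target = np.array([ref_cas[k] for k in shared])
        transform, fit_rmsd = superpose(mobile, target)
        out.append((s.with_coords(transform.apply(s.coords())), fit_rmsd))
    return out
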