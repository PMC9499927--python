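"""Geometric kernels: dihedral angles, backbone torsions, Kabsch superposition, RMSD."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structio import Structure

__all__ = [
    "TorsionRecord",
    "RigidTransform",
    "dihedral",
    "backbone_torsions",
    "superpose",
    "rmsd",
]

COLLINEARITY_TOL = 1e-9  # cross-product norm below which a triple is collinear
PEPTIDE_BOND_BREAK = 2.5  # C(i)-N(i+1) beyond this is a chain break, Angstrom


@dataclass
class TorsionRecord:
    chain_id: str
    residue_seq: int
    residue_name: str
    phi: float | None
    psi: float | None
    omega: float | None  # torsion of the i -> i+1 peptide bond


@dataclass
class RigidTransform:
    rotation: np.ndarray  # 3x3 proper orthonormal
    translation: np.ndarray  # 3-vector

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthonormal")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, IUPAC sign, range (-180, 180].

    cis = 0, trans = 180. Raises for coincident p2/p3 or collinear triples.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    if np.linalg.norm(b2) < 1e-12:
        raise ValueError("dihedral undefined: central atoms coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < COLLINEARITY_TOL or np.linalg.norm(n2) < COLLINEARITY_TOL:
        raise ValueError("dihedral undefined: collinear atom triple")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = n1 @ n2
    y = m1 @ n2
    angle = np.degrees(np.arctan2(y, x))
    if angle <= -180.0:
        angle += 360.0
    return float(angle)


def _safe_dihedral(p1, p2, p3, p4) -> float | None:
    if any(p is None for p in (p1, p2, p3, p4)):
        return None
    try:
        return dihedral(p1, p2, p3, p4)
    except ValueError:
        return None


def backbone_torsions(structure: Structure, chain_id: str) -> list[TorsionRecord]:
    """Per-residue phi/psi/omega for one chain.

    omega(i) is CA(i)-C(i)-N(i+1)-CA(i+1), i.e. the bond linking residue i to
    i+1. Residues missing backbone atoms (or across a chain break) get None
    for the affected angles. Raises KeyError for an absent chain.
    """
    residues = structure.residues(chain_id)
    if not residues:
        raise KeyError(f"chain {chain_id!r} not present in structure")

    def bb(atoms, name):
        for a in atoms:
            if a.name == name and not a.is_hydrogen:
                return a.position
        return None

    keys = [k for k, _ in residues]
    N = [bb(atoms, "N") for _, atoms in residues]
    CA = [bb(atoms, "CA") for _, atoms in residues]
    C = [bb(atoms, "C") for _, atoms in residues]
    names = {k: atoms[0].residue_name for k, atoms in residues}

    def linked(i: int) -> bool:
        """True when residue i is peptide-bonded to residue i+1."""
        if C[i] is None or N[i + 1] is None:
            return False
        return float(np.linalg.norm(C[i] - N[i + 1])) <= PEPTIDE_BOND_BREAK

    records = []
    n = len(residues)
    for i, key in enumerate(keys):
        phi = psi = omega = None
        if i > 0 and linked(i - 1):
            phi = _safe_dihedral(C[i - 1], N[i], CA[i], C[i])
        if i < n - 1 and linked(i):
            psi = _safe_dihedral(N[i], CA[i], C[i], N[i + 1])
            omega = _safe_dihedral(CA[i], C[i], N[i + 1], CA[i + 1])
        records.append(
            TorsionRecord(
                chain_id=chain_id,
                residue_seq=key[1],
                residue_name=names[key],
                phi=phi,
                psi=psi,
                omega=omega,
            )
        )
    return records


def superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition (Kabsch); returns transform and fit RMSD.

    Correspondence is positional; needs >= 3 non-collinear points.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError(f"shape mismatch: {mobile.shape} vs {reference.shape}")
    if mobile.shape[0] < 3:
        raise ValueError("superposition needs at least 3 atoms")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    H = (mobile - mc).T @ (reference - rc)
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-8:
        raise ValueError("degenerate (collinear) point set: rotation is not unique")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    transform = RigidTransform(rotation=R, translation=t)
    fitted = transform.apply(mobile)
    return transform, rmsd(fitted, reference, fit=False)


def rmsd(A: np.ndarray, B: np.ndarray, fit: bool = False) -> float:
    """Root-mean-square deviation between corresponding points, Angstrom."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    if A.shape[0] < 1:
        raise ValueError("need at least one atom")
    if fit:
        _, value = superpose(A, B)
        return value
    return float(np.sqrt(np.mean(np.sum((A - B) ** 2, axis=1))))
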