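"""Deterministic seeded generators for every input the pipeline consumes.

Each generator returns ground-truth labels sufficient to predict the verdict
of the corresponding pipeline stage under default configs, so the full
cascade is testable offline. All generators are pure functions of
(parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import backbone_torsions, dihedral
from .structio import Atom, Ensemble, Pose, Structure, annotate

__all__ = [
    "FixtureLabel",
    "build_peptide",
    "make_pose_library",
    "make_noisy_trajectory",
    "make_probe_trajectory",
    "make_toy_complex",
    "IDEAL_GEOMETRY",
]

# Ideal backbone geometry (bond lengths Angstrom, angles degrees). Exact
# values are repo constants; tests assert self-consistency, not these numbers.
IDEAL_GEOMETRY = {
    "N-CA": 1.458,
    "CA-C": 1.525,
    "C-N": 1.329,
    "C-O": 1.231,
    "CA-CB": 1.530,
    "C-N-CA": 121.7,
    "N-CA-C": 111.0,
    "CA-C-N": 116.6,
    "CA-C-O": 120.8,
    "C-CA-CB": 110.1,
    "N-C-CA-CB": 122.6,  # improper placing CB with L-chirality
}

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclass
class FixtureLabel:
    """Ground truth attached to a generated fixture."""

    kind: str
    truth: dict = field(default_factory=dict)


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d given chain a-b-c, |c-d|, angle(b,c,d) and torsion(a,b,c,d)."""
    angle = np.radians(angle)
    torsion = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [
            -np.cos(angle),
            np.sin(angle) * np.cos(torsion),
            -np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_peptide(
    sequence: str,
    torsions: Sequence[tuple[float, float, float]],
    seed: int = 0,
    chain_id: str = "A",
) -> Structure:
    """Ideal-geometry peptide with prescribed per-residue (phi, psi, omega).

    Backbone (N, CA, C, O, plus CB for non-Gly) is built by sequential
    internal-coordinate placement; measured torsions reproduce the request to
    better than 1e-3 degrees. phi of the first residue and psi/omega of the
    last are ignored. Deterministic; ``seed`` is accepted for interface
    symmetry with the stochastic generators.
    """
    if len(torsions) != len(sequence):
        raise ValueError("torsion list length must match sequence length")
    for code in sequence:
        if code.upper() not in ONE_TO_THREE:
            raise ValueError(f"unknown residue code {code!r}")
    g = IDEAL_GEOMETRY
    n_res = len(sequence)

    # first residue backbone in a canonical frame
    N = [np.zeros(3)]
    CA = [np.array([g["N-CA"], 0.0, 0.0])]
    ang = np.radians(180.0 - g["N-CA-C"])
    C = [CA[0] + g["CA-C"] * np.array([np.cos(ang), np.sin(ang), 0.0])]

    for i in range(n_res - 1):
        _, psi_i, omega_i = torsions[i]
        phi_next = torsions[i + 1][0]
        N.append(_nerf(N[i], CA[i], C[i], g["C-N"], g["CA-C-N"], psi_i))
        CA.append(_nerf(CA[i], C[i], N[i + 1], g["N-CA"], g["C-N-CA"], omega_i))
        C.append(_nerf(C[i], N[i + 1], CA[i + 1], g["CA-C"], g["N-CA-C"], phi_next))

    atoms: list[Atom] = []
    serial = 0

    def add(name, element, pos, res_idx):
        nonlocal serial
        serial += 1
        atoms.append(
            Atom(
                serial=serial,
                name=name,
                element=element,
                residue_name=ONE_TO_THREE[sequence[res_idx].upper()],
                residue_seq=res_idx + 1,
                insertion_code="",
                chain_id=chain_id,
                position=pos,
            )
        )

    for i in range(n_res):
        add("N", "N", N[i], i)
        add("CA", "C", CA[i], i)
        add("C", "C", C[i], i)
        # carbonyl O: anti to the next N (psi + 180), or trans-ish at the C-terminus
        if i < n_res - 1:
            o_torsion = torsions[i][1] + 180.0
        else:
            o_torsion = 0.0
        add("O", "O", _nerf(N[i], CA[i], C[i], g["C-O"], g["CA-C-O"], o_torsion), i)
        if sequence[i].upper() != "G":
            cb = _nerf(N[i], C[i], CA[i], g["CA-CB"], g["C-CA-CB"], g["N-C-CA-CB"])
            add("CB", "C", cb, i)

    return annotate(Structure(atoms=atoms, label=f"peptide-{sequence}"))


# ---------------------------------------------------------------------------
# pose libraries with labeled defects
# ---------------------------------------------------------------------------

_CLEAN_PHI_PSI = (-120.0, 130.0)  # comfortably inside the beta region
# bridge region: disallowed in the bundled map yet sterically mild, so the
# injected defect trips only the Ramachandran filter
_BAD_PHI_PSI = (-75.0, 45.0)


def _clean_torsions(n_res: int, rng: np.random.Generator) -> list[tuple[float, float, float]]:
    phi0, psi0 = _CLEAN_PHI_PSI
    return [
        (phi0 + rng.uniform(-8, 8), psi0 + rng.uniform(-8, 8), 180.0 + rng.uniform(-10, 10))
        for _ in range(n_res)
    ]


def _inject_clash(structure: Structure, rng: np.random.Generator) -> Structure:
    """Move the CB of residue 2 to 1.0 A from the C of the last residue."""
    atoms = structure.atoms
    target = next(a for a in atoms if a.residue_seq == max(x.residue_seq for x in atoms) and a.name == "C")
    coords = structure.coords()
    for i, a in enumerate(atoms):
        if a.residue_seq == 2 and a.name == "CB":
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            coords[i] = target.position + direction * 1.0
            break
    return structure.with_coords(coords)


def make_pose_library(
    n_compounds: int,
    poses_per_compound: int,
    defect_rates: dict[str, float] | None = None,
    score_distribution: tuple[float, float] = (-8.0, 1.5),
    seed: int = 0,
    sequence: str = "AAAAA",
) -> tuple[dict[str, list[Pose]], FixtureLabel]:
    """Decoy pose libraries with known per-pose defect labels.

    ``defect_rates`` holds independent probabilities for the keys
    "ramachandran", "omega", "clash". Each pose is built clean and then
    corrupted per drawn defects; construction is verified (and re-drawn up to
    a bounded number of times) so injected defects never spill into other
    filters — labels therefore exactly determine per-filter verdicts.
    """
    from .posefilter import FilterConfig, evaluate_pose

    rates = {"ramachandran": 0.0, "omega": 0.0, "clash": 0.0}
    if defect_rates:
        unknown = set(defect_rates) - set(rates)
        if unknown:
            raise ValueError(f"unknown defect keys: {sorted(unknown)}")
        rates.update(defect_rates)
    for k, v in rates.items():
        if not 0 <= v <= 1:
            raise ValueError(f"defect rate {k} must be in [0, 1]")

    rng = np.random.default_rng(seed)
    config = FilterConfig()
    library: dict[str, list[Pose]] = {}
    truth: dict[str, list[dict]] = {}
    mu, sd = score_distribution

    for ci in range(n_compounds):
        compound_id = f"C{ci + 1:03d}"
        scored: list[tuple[float, Structure, dict]] = []
        for _pi in range(poses_per_compound):
            defects = {k: bool(rng.random() < rates[k]) for k in ("ramachandran", "omega", "clash")}
            score = float(rng.normal(mu, sd))
            for _attempt in range(50):
                torsions = _clean_torsions(len(sequence), rng)
                if defects["ramachandran"]:
                    torsions[2] = (_BAD_PHI_PSI[0], _BAD_PHI_PSI[1], torsions[2][2])
                if defects["omega"]:
                    # defect on the 4->5 bond, far from the torsion defect at residue 3
                    torsions[3] = (torsions[3][0], torsions[3][1], float(rng.choice([0.0, 100.0, -100.0])))
                structure = build_peptide(sequence, torsions, seed=0)
                if defects["clash"]:
                    structure = _inject_clash(structure, rng)
                probe = Pose(ligand=structure, score=score, rank=1, compound_id=compound_id)
                verdict = evaluate_pose(probe, config=config)
                measured = {
                    "ramachandran": not verdict.pass_ramachandran,
                    "omega": not verdict.pass_peptide_bonds,
                    "clash": not verdict.pass_clashes,
                }
                if measured == defects:
                    break
            else:  # pragma: no cover - generator guarantee
                raise RuntimeError("could not realize requested defect pattern")
            scored.append((score, structure, defects))
        scored.sort(key=lambda t: t[0])
        poses = []
        labels = []
        for rank, (score, structure, defects) in enumerate(scored, start=1):
            poses.append(Pose(ligand=structure, score=score, rank=rank, compound_id=compound_id))
            labels.append({"rank": rank, "score": score, "defects": defects})
        library[compound_id] = poses
        truth[compound_id] = labels
    return library, FixtureLabel(kind="pose_library", truth={"poses": truth, "rates": rates})


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def make_noisy_trajectory(
    reference: Structure,
    sigma: float,
    n_frames: int,
    frame_interval: float = 1.0,
    seed: int = 0,
) -> tuple[Ensemble, FixtureLabel]:
    """Frames = reference + iid per-coordinate Gaussian noise of scale sigma."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    ref = reference.coords()
    frames = [ref + rng.normal(0.0, sigma, size=ref.shape) if sigma > 0 else ref.copy() for _ in range(n_frames)]
    ens = Ensemble(topology=reference, frames=frames, frame_interval=frame_interval, label="noisy")
    return ens, FixtureLabel(kind="noisy_trajectory", truth={"sigma": sigma, "n_frames": n_frames})


def make_probe_trajectory(
    protein: Structure,
    site: np.ndarray,
    enrichment: float,
    n_probes: int,
    n_frames: int,
    seed: int = 0,
    site_sigma: float = 1.0,
    margin: float = 8.0,
    probe_type: str = "positive",
) -> tuple[Ensemble, FixtureLabel]:
    """Protein + single-atom organic probes with a planted binding hotspot.

    Per frame each probe sits at the planted site (Gaussian, sigma 1 A) with
    probability ``enrichment``, otherwise uniformly in the box (protein
    bounding box + margin).
    """
    if not 0 <= enrichment <= 1:
        raise ValueError("enrichment must be in [0, 1]")
    site = np.asarray(site, dtype=float)
    coords = protein.coords()
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    if np.any(site < lo) or np.any(site > hi):
        raise ValueError("planted site lies outside the probe box")

    rng = np.random.default_rng(seed)
    atoms = list(protein.atoms)
    serial = max((a.serial for a in atoms), default=0)
    for p in range(n_probes):
        serial += 1
        atoms.append(
            Atom(
                serial=serial,
                name="C1",
                element="C",
                residue_name="PRB",
                residue_seq=p + 1,
                insertion_code="",
                chain_id="X",
                position=np.zeros(3),
                hetatm=True,
            )
        )
    topology = Structure(atoms=atoms, label="probe-system")
    n_protein = len(protein.atoms)
    frames = []
    for _f in range(n_frames):
        frame = np.empty((len(atoms), 3))
        frame[:n_protein] = coords
        for p in range(n_probes):
            if rng.random() < enrichment:
                pos = site + rng.normal(0.0, site_sigma, size=3)
            else:
                pos = rng.uniform(lo, hi)
            frame[n_protein + p] = pos
        frames.append(frame)
    ens = Ensemble(topology=topology, frames=frames, frame_interval=1.0, label="probe-traj")
    label = FixtureLabel(
        kind="probe_trajectory",
        truth={
            "site": site.tolist(),
            "enrichment": enrichment,
            "n_probes": n_probes,
            "probe_chain": "X",
            "probe_type": probe_type,
        },
    )
    return ens, label


# ---------------------------------------------------------------------------
# toy complexes with planted contacts
# ---------------------------------------------------------------------------

_RES_OFFSETS = {  # local atom offsets; CA is the tip pointing toward the partner
    "N": np.array([-0.8, 0.0, 0.0]),
    "C": np.array([0.8, 0.0, 0.0]),
    "O": np.array([0.0, 0.0, 0.8]),
}
_TIP = 0.8  # CA offset along the inter-chain axis


def _place_residue(atoms, center, tip_dir, chain_id, res_seq, serial_start):
    serial = serial_start
    positions = {"CA": center + _TIP * tip_dir}
    positions.update({name: center + off for name, off in _RES_OFFSETS.items()})
    for name in ("N", "CA", "C", "O"):
        serial += 1
        atoms.append(
            Atom(
                serial=serial,
                name=name,
                element=name[0],
                residue_name="GLY",
                residue_seq=res_seq,
                insertion_code="",
                chain_id=chain_id,
                position=positions[name],
            )
        )
    return serial


def make_toy_complex(
    n_receptor_res: int,
    n_partner_res: int,
    planted_contacts: Sequence[tuple[int, int, float]],
    seed: int = 0,
    cutoff: float = 4.0,
) -> tuple[Structure, FixtureLabel]:
    """Two-chain complex in which exactly the planted residue pairs touch.

    ``planted_contacts`` lists (receptor_seq, partner_seq, distance); the
    minimum heavy-atom distance of each planted pair equals the requested
    distance exactly (tip CA atoms face each other), and every other
    cross-chain residue pair stays above cutoff + 2 A. Receptor is chain A,
    partner chain B.
    """
    spacing = max(12.0, cutoff + 8.0)
    far_y = cutoff + 10.0 + 2 * _TIP
    planted_by_partner: dict[int, tuple[int, float]] = {}
    for ri, pj, d in planted_contacts:
        if d <= 0:
            raise ValueError("planted distance must be > 0")
        if not (1 <= ri <= n_receptor_res and 1 <= pj <= n_partner_res):
            raise ValueError(f"planted pair ({ri}, {pj}) out of range")
        if pj in planted_by_partner:
            raise ValueError(f"partner residue {pj} planted twice: infeasible")
        if d >= far_y - 2 * _TIP - 1.0:
            raise ValueError(f"planted distance {d} too large for the layout")
        planted_by_partner[pj] = (ri, d)
    planted_receptors = [ri for ri, _ in planted_by_partner.values()]
    if len(set(planted_receptors)) != len(planted_receptors):
        raise ValueError("a receptor residue may host at most one planted contact")

    atoms: list[Atom] = []
    serial = 0
    up = np.array([0.0, 1.0, 0.0])
    for i in range(1, n_receptor_res + 1):
        center = np.array([spacing * (i - 1), 0.0, 0.0])
        serial = _place_residue(atoms, center, up, "A", i, serial)
    for j in range(1, n_partner_res + 1):
        if j in planted_by_partner:
            ri, d = planted_by_partner[j]
            # tip-to-tip distance along y equals d exactly
            center = np.array([spacing * (ri - 1), 2 * _TIP + d, 0.0])
        else:
            center = np.array([spacing * (j - 1), far_y, 0.0])
        serial = _place_residue(atoms, center, -up, "B", j, serial)

    structure = annotate(Structure(atoms=atoms, label="toy-complex"))
    label = FixtureLabel(
        kind="toy_complex",
        truth={
            "planted": [(ri, pj, d) for pj, (ri, d) in sorted(planted_by_partner.items())],
            "receptor_chain": "A",
            "partner_chain": "B",
            "cutoff": cutoff,
        },
    )
    return structure, label
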