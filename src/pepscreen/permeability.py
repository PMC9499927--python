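"""Shrake-Rupley accessible surface area, polar-area restriction, and
conformer-ensemble permeability verdicts.

Sphere sampling uses a deterministic golden-spiral lattice so results are
bit-for-bit reproducible at a fixed point count. The ensemble-averaged polar
area (pol_asa_avg) carries two strict thresholds: < 150 A^2 passes the
permeability screen, < 130 A^2 passes the synthesis cut.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structio import Ensemble, Structure, annotate

__all__ = [
    "PermeabilityConfig",
    "SasaResult",
    "PermeabilityVerdict",
    "sphere_points",
    "sasa",
    "extract_snapshots",
    "combine_ensembles",
    "ensemble_polar_asa",
]


@dataclass
class PermeabilityConfig:
    probe_radius: float = 1.4  # Angstrom
    n_sphere_points: int = 960
    screen_threshold: float = 150.0  # A^2, strict <
    synthesis_threshold: float = 130.0  # A^2, strict <
    snapshot_interval: float = 4.0  # ps

    def __post_init__(self) -> None:
        if self.probe_radius < 0:
            raise ValueError("probe_radius must be >= 0")
        if self.n_sphere_points < 1:
            raise ValueError("n_sphere_points must be >= 1")
        if not 0 < self.synthesis_threshold <= self.screen_threshold:
            raise ValueError("need 0 < synthesis_threshold <= screen_threshold")


@dataclass
class SasaResult:
    per_atom_area: np.ndarray  # A^2
    total_area: float
    polar_area: float
    probe_radius: float
    n_sphere_points: int

    @property
    def apolar_area(self) -> float:
        return self.total_area - self.polar_area


@dataclass
class PermeabilityVerdict:
    pol_asa_avg: float
    n_frames: int
    permeable_screen: bool  # pol_asa_avg < screen_threshold
    pass_synthesis_cut: bool  # pol_asa_avg < synthesis_threshold
    per_frame_polar_area: np.ndarray | None = None


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (golden spiral), (n, 3)."""
    i = np.arange(n, dtype=float) + 0.5
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = golden * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def sasa(structure: Structure, config: PermeabilityConfig | None = None) -> SasaResult:
    """Shrake-Rupley solvent-accessible surface area.

    Per-atom area = 4 pi (r_i + probe)^2 * (accessible points / total points).
    Hydrogens are included when present. Atoms must be annotated (radius and
    polarity); unannotated input raises.
    """
    config = config or PermeabilityConfig()
    atoms = structure.atoms
    if not atoms:
        raise ValueError("empty structure")
    if any(a.vdw_radius is None or a.is_polar is None for a in atoms):
        raise ValueError("structure must be annotated (vdw_radius, is_polar) before SASA")

    coords = structure.coords()
    radii = np.array([a.vdw_radius for a in atoms]) + config.probe_radius
    unit = sphere_points(config.n_sphere_points)
    tree = cKDTree(coords)
    per_atom = np.zeros(len(atoms))
    max_r = radii.max()
    for i in range(len(atoms)):
        neighbors = [j for j in tree.query_ball_point(coords[i], radii[i] + max_r) if j != i]
        pts = coords[i] + radii[i] * unit
        accessible = np.ones(config.n_sphere_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 >= radii[j] ** 2
        frac = accessible.sum() / config.n_sphere_points
        per_atom[i] = 4.0 * np.pi * radii[i] ** 2 * frac
    polar = float(sum(per_atom[i] for i, a in enumerate(atoms) if a.is_polar))
    return SasaResult(
        per_atom_area=per_atom,
        total_area=float(per_atom.sum()),
        polar_area=polar,
        probe_radius=config.probe_radius,
        n_sphere_points=config.n_sphere_points,
    )


def extract_snapshots(traj: Ensemble, interval: float) -> Ensemble:
    """Take one frame every ``interval`` ps, excluding t=0.

    Frame i sits at time (i+1)*frame_interval; frames at interval, 2*interval,
    ... are kept, giving floor(duration / interval) snapshots. The interval
    must be a positive multiple of the frame spacing.
    """
    dt = traj.frame_interval
    if interval < dt:
        raise ValueError(f"interval {interval} ps is below the frame spacing {dt} ps")
    step = interval / dt
    if abs(step - round(step)) > 1e-9:
        raise ValueError(f"interval {interval} ps is not a multiple of the frame spacing {dt} ps")
    step = int(round(step))
    frames = [traj.frames[i] for i in range(step - 1, traj.n_frames, step)]
    return Ensemble(
        topology=traj.topology,
        frames=frames,
        frame_interval=interval,
        label=traj.label,
    )


def combine_ensembles(ensembles: list[Ensemble]) -> Ensemble:
    """Concatenate frames of topology-identical ensembles, input order preserved."""
    if not ensembles:
        raise ValueError("no ensembles to combine")
    first = ensembles[0]
    sig = [(a.chain_id, a.residue_seq, a.name) for a in first.topology.atoms]
    frames: list[np.ndarray] = []
    for e in ensembles:
        if [(a.chain_id, a.residue_seq, a.name) for a in e.topology.atoms] != sig:
            raise ValueError(f"ensemble {e.label!r}: topology mismatch")
        frames.extend(e.frames)
    return Ensemble(
        topology=first.topology,
        frames=frames,
        frame_interval=first.frame_interval,
        label=first.label,
    )


def ensemble_polar_asa(
    ensemble: Ensemble, config: PermeabilityConfig | None = None
) -> PermeabilityVerdict:
    """Average per-frame polar accessible area over a conformer ensemble."""
    config = config or PermeabilityConfig()
    if ensemble.n_frames == 0:
        raise ValueError("empty ensemble")
    topo = ensemble.topology
    if any(a.vdw_radius is None or a.is_polar is None for a in topo.atoms):
        topo = annotate(topo)
    series = np.empty(ensemble.n_frames)
    for i in range(ensemble.n_frames):
        series[i] = sasa(topo.with_coords(ensemble.frames[i]), config).polar_area
    avg = float(series.mean())
    return PermeabilityVerdict(
        pol_asa_avg=avg,
        n_frames=ensemble.n_frames,
        permeable_screen=avg < config.screen_threshold,
        pass_synthesis_cut=avg < config.synthesis_threshold,
        per_frame_polar_area=series,
    )
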