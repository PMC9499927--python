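"""Ligand binding-stability classification from complex trajectories.

Per frame the complex is superposed onto the reference docked pose using
receptor heavy atoms, then the unfitted heavy-atom RMSD of the ligand is
taken against the reference ligand — ligand drift from its docked binding
mode counts in full. The verdict averages the series over a trailing window
(default: trailing 50%, i.e. the last 1.5 ns of a 3-ns run) and calls the
compound a stable binder when the mean is strictly below the threshold
(default 3.0 Angstrom).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import rmsd, superpose
from .structio import Ensemble, Structure

__all__ = ["StabilityConfig", "StabilityVerdict", "ligand_rmsd_series", "assess_stability"]


@dataclass
class StabilityConfig:
    ligand_selection: str = "L"  # chain id of the ligand
    receptor_selection: str = "A"  # chain id of the receptor
    threshold: float = 3.0  # Angstrom, strict <
    window_fraction: float | None = 0.5  # trailing fraction of frames
    window_ps: float | None = None  # or an explicit trailing duration
    align_on_receptor: bool = True

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.window_fraction is not None and not 0 < self.window_fraction <= 1:
            raise ValueError("window_fraction must be in (0, 1]")

    def window_frames(self, n_frames: int, frame_interval: float) -> int:
        if self.window_ps is not None:
            w = int(round(self.window_ps / frame_interval))
        else:
            w = int(np.floor(n_frames * (self.window_fraction or 0.5) + 1e-9))
        w = max(w, 1)
        if w > n_frames:
            raise ValueError(f"window of {w} frames exceeds series length {n_frames}")
        return w


@dataclass
class StabilityVerdict:
    lig_rmsd_series: np.ndarray  # per-frame Angstrom, full trajectory
    lig_rmsd_avg: float  # mean over the trailing window
    window_frames: int
    stable: bool


def _chain_heavy_indices(structure: Structure, chain_id: str) -> list[int]:
    return [
        i
        for i, a in enumerate(structure.atoms)
        if a.chain_id == chain_id and not a.is_hydrogen and a.element != "H" and not a.name.startswith("H")
    ]


def ligand_rmsd_series(
    traj: Ensemble, reference: Structure, config: StabilityConfig | None = None
) -> np.ndarray:
    """Per-frame ligand heavy-atom RMSD versus the reference docked complex.

    Atoms are matched between the trajectory topology and the reference by
    (chain, residue, insertion code, atom name).
    """
    config = config or StabilityConfig()
    topo = traj.topology
    lig_idx = _chain_heavy_indices(topo, config.ligand_selection)
    rec_idx = _chain_heavy_indices(topo, config.receptor_selection)
    if not lig_idx:
        raise ValueError(f"ligand selection {config.ligand_selection!r} matched no heavy atoms")
    if not rec_idx:
        raise ValueError(f"receptor selection {config.receptor_selection!r} matched no heavy atoms")

    ref_by_key = {
        (a.chain_id, a.residue_seq, a.insertion_code, a.name): a.position
        for a in reference.atoms
    }

    def ref_coords(indices):
        out = []
        for i in indices:
            a = topo.atoms[i]
            key = (a.chain_id, a.residue_seq, a.insertion_code, a.name)
            if key not in ref_by_key:
                raise ValueError(f"reference is missing atom {key}")
            out.append(ref_by_key[key])
        return np.array(out)

    ref_lig = ref_coords(lig_idx)
    ref_rec = ref_coords(rec_idx)

    series = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        frame = traj.frames[f]
        lig = frame[lig_idx]
        if config.align_on_receptor:
            transform, _ = superpose(frame[rec_idx], ref_rec)
            lig = transform.apply(lig)
        series[f] = rmsd(lig, ref_lig, fit=False)
    return series


def assess_stability(
    series: np.ndarray,
    config: StabilityConfig | None = None,
    frame_interval: float = 1.0,
) -> StabilityVerdict:
    """Average the series over the trailing window; stable iff mean < threshold."""
    config = config or StabilityConfig()
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or series.size == 0:
        raise ValueError("series must be a non-empty 1-D array")
    w = config.window_frames(series.size, frame_interval)
    avg = float(series[-w:].mean())
    return StabilityVerdict(
        lig_rmsd_series=series,
        lig_rmsd_avg=avg,
        window_frames=w,
        stable=avg < config.threshold,
    )
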