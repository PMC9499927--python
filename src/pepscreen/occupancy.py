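"""Probe-occupancy mapping from mixed-solvent ensembles.

Each probe molecule's heavy-atom geometric center is binned into a voxel grid
for every frame in a trailing window (default: last 50% of the trajectory).
Voxels concentrating at least a threshold fraction of a probe type's visits
are merged into connected components and reported as hotspot sites together
with their flanking protein residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .structio import Ensemble, Structure

__all__ = [
    "GridSpec",
    "OccupancyGrid",
    "HotspotSite",
    "accumulate_occupancy",
    "hotspot_sites",
    "probe_groups_by_chain",
    "write_dx",
]


@dataclass
class GridSpec:
    origin: np.ndarray  # Angstrom
    spacing: float = 1.0
    shape: tuple[int, int, int] = (32, 32, 32)
    window: float = 0.5  # trailing fraction of frames

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if not 0 < self.window <= 1:
            raise ValueError("window must be in (0, 1]")

    @classmethod
    def around(cls, structure: Structure, spacing: float = 1.0, margin: float = 8.0, window: float = 0.5) -> "GridSpec":
        """Grid covering the structure's bounding box plus a margin."""
        coords = structure.coords()
        lo = coords.min(axis=0) - margin
        hi = coords.max(axis=0) + margin
        shape = tuple(int(np.ceil((hi[k] - lo[k]) / spacing)) for k in range(3))
        return cls(origin=lo, spacing=spacing, shape=shape, window=window)

    def voxel_index(self, point: np.ndarray) -> tuple[int, int, int] | None:
        """Voxel containing a point, or None when outside the grid."""
        idx = np.floor((np.asarray(point) - self.origin) / self.spacing).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.asarray(self.shape)):
            return None
        return tuple(int(v) for v in idx)

    def voxel_center(self, idx: Sequence[int]) -> np.ndarray:
        return self.origin + self.spacing * (np.asarray(idx, dtype=float) + 0.5)


@dataclass
class OccupancyGrid:
    spec: GridSpec
    counts: dict[str, np.ndarray]  # probe type -> voxel visit counts
    out_of_grid: dict[str, int]  # sentinel bin per probe type
    n_frames_used: int
    n_probes: dict[str, int]

    def fraction(self, probe_type: str) -> np.ndarray:
        total = self.n_frames_used * self.n_probes[probe_type]
        return self.counts[probe_type] / total if total else self.counts[probe_type] * 0.0


@dataclass
class HotspotSite:
    probe_type: str
    center: np.ndarray  # peak voxel center, Angstrom
    peak_fraction: float
    n_voxels: int
    flanking_residues: list[tuple[str, int, str]]  # sorted by distance to peak


def probe_groups_by_chain(
    topology: Structure, chain_to_type: Mapping[str, str]
) -> dict[str, list[np.ndarray]]:
    """Build probe groups from chains: one molecule per residue of each chain."""
    groups: dict[str, list[np.ndarray]] = {t: [] for t in set(chain_to_type.values())}
    by_residue: dict[str, dict[tuple, list[int]]] = {c: {} for c in chain_to_type}
    for i, a in enumerate(topology.atoms):
        if a.chain_id in by_residue and not a.is_hydrogen:
            by_residue[a.chain_id].setdefault(a.residue_key, []).append(i)
    for chain, ptype in chain_to_type.items():
        for idx in by_residue[chain].values():
            groups[ptype].append(np.array(idx, dtype=int))
    return groups


def accumulate_occupancy(
    ensemble: Ensemble,
    probe_groups: Mapping[str, Sequence[np.ndarray]],
    spec: GridSpec,
) -> OccupancyGrid:
    """Bin per-probe geometric centers into the grid over the trailing window.

    ``probe_groups`` maps probe type -> one atom-index array per probe
    molecule. Every probe lands in exactly one voxel per frame; positions
    outside the grid are tallied in a per-type sentinel bin so counts are
    conserved.
    """
    for ptype, groups in probe_groups.items():
        if not groups:
            raise ValueError(f"probe type {ptype!r}: empty selection")
    n = ensemble.n_frames
    n_used = max(1, int(n * spec.window + 1e-9))
    start = n - n_used
    counts = {t: np.zeros(spec.shape, dtype=np.int64) for t in probe_groups}
    sentinel = {t: 0 for t in probe_groups}
    for f in range(start, n):
        frame = ensemble.frames[f]
        for ptype, groups in probe_groups.items():
            for idx in groups:
                center = frame[idx].mean(axis=0)
                voxel = spec.voxel_index(center)
                if voxel is None:
                    sentinel[ptype] += 1
                else:
                    counts[ptype][voxel] += 1
    return OccupancyGrid(
        spec=spec,
        counts=counts,
        out_of_grid=sentinel,
        n_frames_used=n_used,
        n_probes={t: len(g) for t, g in probe_groups.items()},
    )


def hotspot_sites(
    grid: OccupancyGrid,
    protein: Structure,
    report_radius: float = 5.0,
    min_fraction: float = 0.2,
) -> list[HotspotSite]:
    """Voxels with occupancy fraction >= min_fraction, merged into connected
    components and ranked by peak fraction; flanking residues are protein
    residues with any heavy atom within report_radius of the component peak."""
    heavy = [a for a in protein.atoms if not a.is_hydrogen]
    sites: list[HotspotSite] = []
    structure26 = np.ones((3, 3, 3), dtype=bool)
    for ptype in grid.counts:
        frac = grid.fraction(ptype)
        mask = frac >= min_fraction
        if not mask.any():
            continue
        labels, n_components = ndimage.label(mask, structure=structure26)
        for comp in range(1, n_components + 1):
            comp_mask = labels == comp
            comp_frac = np.where(comp_mask, frac, -1.0)
            peak_idx = np.unravel_index(int(np.argmax(comp_frac)), frac.shape)
            center = grid.spec.voxel_center(peak_idx)
            flank = []
            for a in heavy:
                d = float(np.linalg.norm(a.position - center))
                if d <= report_radius:
                    flank.append((d, (a.chain_id, a.residue_seq, a.residue_name)))
            seen: dict[tuple, float] = {}
            for d, rid in flank:
                if rid not in seen or d < seen[rid]:
                    seen[rid] = d
            residues = [rid for rid, _d in sorted(seen.items(), key=lambda kv: kv[1])]
            sites.append(
                HotspotSite(
                    probe_type=ptype,
                    center=center,
                    peak_fraction=float(frac[peak_idx]),
                    n_voxels=int(comp_mask.sum()),
                    flanking_residues=residues,
                )
            )
    sites.sort(key=lambda s: -s.peak_fraction)
    return sites


def write_dx(grid: OccupancyGrid, probe_type: str, path) -> None:
    """Write one probe type's occupancy fractions as an OpenDX scalar field."""
    spec = grid.spec
    frac = grid.fraction(probe_type)
    nx, ny, nz = spec.shape
    with open(path, "w") as fh:
        fh.write(f"# occupancy fraction for probe type {probe_type}\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        ox, oy, oz = spec.origin
        fh.write(f"origin {ox:.3f} {oy:.3f} {oz:.3f}\n")
        fh.write(f"delta {spec.spacing:.3f} 0 0\n")
        fh.write(f"delta 0 {spec.spacing:.3f} 0\n")
        fh.write(f"delta 0 0 {spec.spacing:.3f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items {frac.size} data follows\n")
        flat = frac.ravel(order="C")
        for i in range(0, flat.size, 3):
            fh.write(" ".join(f"{v:.6e}" for v in flat[i : i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')
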