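import numpy as np
import pytest

from pepscreen.permeability import (
    PermeabilityConfig,
    combine_ensembles,
    ensemble_polar_asa,
    extract_snapshots,
    sasa,
    sphere_points,
)
from pepscreen.structio import VDW_RADII, Ensemble, Structure, annotate
from pepscreen.synth import build_peptide, make_noisy_trajectory

from conftest import make_atom


def isolated_sphere_area(radius, probe=1.4):
    return 4.0 * np.pi * (radius + probe) ** 2


def mc_total_sasa(structure, probe, n_samples, seed):
    """Monte-Carlo surface integration oracle, independent of the lattice method."""
    rng = np.random.default_rng(seed)
    coords = structure.coords()
    radii = np.array([a.vdw_radius for a in structure.atoms]) + probe
    total = 0.0
    for i in range(len(coords)):
        v = rng.normal(size=(n_samples, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        pts = coords[i] + radii[i] * v
        free = np.ones(n_samples, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            free &= np.sum((pts - coords[j]) ** 2, axis=1) >= radii[j] ** 2
        total += 4.0 * np.pi * radii[i] ** 2 * free.mean()
    return total


class TestSpherePoints:
    def test_unit_norm(self):
        pts = sphere_points(960)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)

    def test_deterministic(self):
        np.testing.assert_array_equal(sphere_points(100), sphere_points(100))

    def test_centroid_near_origin(self):
        assert np.linalg.norm(sphere_points(960).mean(axis=0)) < 1e-2


class TestSasa:
    def test_isolated_carbon_closed_form(self, single_carbon):
        result = sasa(single_carbon)
        expected = isolated_sphere_area(1.70)
        assert result.total_area == pytest.approx(expected, rel=0.005)
        assert expected == pytest.approx(120.76, abs=0.05)

    @pytest.mark.parametrize("element", sorted(VDW_RADII))
    def test_isolated_sphere_every_element(self, element):
        s = annotate(Structure(atoms=[make_atom(name=element, element=element)]))
        result = sasa(s)
        assert result.total_area == pytest.approx(isolated_sphere_area(VDW_RADII[element]), rel=0.005)

    def test_distant_spheres_unoccluded(self):
        far = 2 * (1.70 + 1.4) + 1.0
        s = annotate(
            Structure(atoms=[make_atom(serial=1), make_atom(serial=2, pos=(far, 0, 0))])
        )
        result = sasa(s)
        iso = isolated_sphere_area(1.70)
        np.testing.assert_allclose(result.per_atom_area, iso, rtol=0.005)

    def test_touching_spheres_occluded(self):
        s = annotate(Structure(atoms=[make_atom(serial=1), make_atom(serial=2, pos=(2.0, 0, 0))]))
        result = sasa(s)
        assert result.total_area < 2 * isolated_sphere_area(1.70)

    def test_random_cluster_against_mc_oracle(self, rng):
        atoms = [
            make_atom(serial=i + 1, pos=tuple(rng.uniform(0, 6, size=3))) for i in range(20)
        ]
        s = annotate(Structure(atoms=atoms))
        result = sasa(s)
        oracle = mc_total_sasa(s, 1.4, 100_000, seed=99)
        assert result.total_area == pytest.approx(oracle, rel=0.02)

    def test_polar_plus_apolar_equals_total(self, helical_peptide):
        result = sasa(helical_peptide)
        assert result.polar_area + result.apolar_area == pytest.approx(result.total_area, abs=1e-9)
        assert result.polar_area <= result.total_area

    def test_burying_polar_atom_never_increases_polar_area(self, helical_peptide):
        base = sasa(helical_peptide)
        # park a big apolar atom right next to a polar N
        n_atom = next(a for a in helical_peptide.atoms if a.name == "N")
        blocker = make_atom(serial=999, name="C", element="C", resseq=99,
                            pos=tuple(n_atom.position + np.array([2.0, 0, 0])))
        buried = annotate(Structure(atoms=helical_peptide.atoms + [blocker]))
        result = sasa(buried)
        assert result.polar_area <= base.polar_area + 1e-9

    def test_point_count_convergence(self, helical_peptide):
        coarse = sasa(helical_peptide, PermeabilityConfig(n_sphere_points=960))
        fine = sasa(helical_peptide, PermeabilityConfig(n_sphere_points=10_000))
        assert coarse.total_area == pytest.approx(fine.total_area, rel=0.005)

    def test_unannotated_raises(self):
        s = Structure(atoms=[make_atom()])
        with pytest.raises(ValueError, match="annotated"):
            sasa(s)


class TestExtractSnapshots:
    def _traj(self, n_frames, dt):
        topo = annotate(Structure(atoms=[make_atom()]))
        frames = [np.full((1, 3), float(i)) for i in range(n_frames)]
        return Ensemble(topology=topo, frames=frames, frame_interval=dt)

    def test_100ps_at_4ps_gives_25(self):
        out = extract_snapshots(self._traj(100, 1.0), 4.0)
        assert out.n_frames == 25

    def test_2ns_at_4ps_gives_500(self):
        out = extract_snapshots(self._traj(1000, 2.0), 4.0)
        assert out.n_frames == 500

    def test_interval_equals_duration_gives_one(self):
        out = extract_snapshots(self._traj(10, 1.0), 10.0)
        assert out.n_frames == 1

    def test_t0_excluded(self):
        out = extract_snapshots(self._traj(8, 2.0), 4.0)
        # 16-ps span, snapshots at 4/8/12/16 ps = input indices 1, 3, 5, 7
        assert out.n_frames == 4
        assert [f[0, 0] for f in out.frames] == [1.0, 3.0, 5.0, 7.0]

    def test_interval_below_spacing_raises(self):
        with pytest.raises(ValueError, match="below"):
            extract_snapshots(self._traj(10, 2.0), 1.0)

    def test_non_multiple_interval_raises(self):
        with pytest.raises(ValueError, match="multiple"):
            extract_snapshots(self._traj(10, 2.0), 5.0)


class TestCombineEnsembles:
    def _ens(self, n_frames, value=0.0):
        topo = annotate(Structure(atoms=[make_atom()]))
        return Ensemble(topology=topo, frames=[np.full((1, 3), value)] * n_frames, frame_interval=4.0)

    def test_25_by_500_gives_12500(self):
        combined = combine_ensembles([self._ens(500) for _ in range(25)])
        assert combined.n_frames == 12_500

    def test_single_unchanged(self):
        e = self._ens(7)
        combined = combine_ensembles([e])
        assert combined.n_frames == 7

    def test_order_preserved(self):
        combined = combine_ensembles([self._ens(2, 1.0), self._ens(3, 2.0)])
        assert [f[0, 0] for f in combined.frames] == [1.0, 1.0, 2.0, 2.0, 2.0]

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            combine_ensembles([])

    def test_topology_mismatch_raises(self):
        topo2 = annotate(Structure(atoms=[make_atom(name="N", element="N")]))
        other = Ensemble(topology=topo2, frames=[np.zeros((1, 3))], frame_interval=4.0)
        with pytest.raises(ValueError, match="mismatch"):
            combine_ensembles([self._ens(1), other])


class TestEnsemblePolarAsa:
    def test_identical_frames_equal_single_frame(self, helical_peptide):
        single = sasa(helical_peptide).polar_area
        ens = Ensemble(topology=helical_peptide, frames=[helical_peptide.coords()] * 3, frame_interval=4.0)
        verdict = ensemble_polar_asa(ens)
        assert verdict.pol_asa_avg == pytest.approx(single, abs=1e-9)

    def test_average_of_frames_and_strict_screen(self, helical_peptide, monkeypatch):
        # frames engineered to average exactly at the screen threshold
        ens = Ensemble(topology=helical_peptide, frames=[helical_peptide.coords()] * 2, frame_interval=4.0)
        verdict = ensemble_polar_asa(ens)
        forced = verdict.per_frame_polar_area
        # construct a synthetic verdict at the boundary via the config
        cfg = PermeabilityConfig(screen_threshold=float(np.mean(forced)))
        boundary = ensemble_polar_asa(ens, cfg)
        assert not boundary.permeable_screen  # strict <

    def test_matches_frame_by_frame_recomputation(self, helical_peptide):
        ens, _ = make_noisy_trajectory(helical_peptide, 0.3, 4, seed=5)
        ens = Ensemble(topology=ens.topology, frames=ens.frames, frame_interval=4.0)
        verdict = ensemble_polar_asa(ens)
        recomputed = [
            sasa(helical_peptide.with_coords(f)).polar_area for f in ens.frames
        ]
        assert verdict.pol_asa_avg == pytest.approx(float(np.mean(recomputed)), abs=1e-9)
        np.testing.assert_allclose(verdict.per_frame_polar_area, recomputed, atol=1e-9)

    def test_empty_ensemble_raises(self, helical_peptide):
        ens = Ensemble(topology=helical_peptide, frames=[], frame_interval=4.0)
        with pytest.raises(ValueError):
            ensemble_polar_asa(ens)

    def test_synthesis_cut_stricter_than_screen(self, helical_peptide):
        ens = Ensemble(topology=helical_peptide, frames=[helical_peptide.coords()], frame_interval=4.0)
        verdict = ensemble_polar_asa(ens)
        if verdict.pass_synthesis_cut:
            assert verdict.permeable_screen
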