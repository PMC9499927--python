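import numpy as np
import pytest

from pepscreen.posefilter import (
    BackboneError,
    FilterConfig,
    RamachandranMap,
    apply_energy_cut,
    build_default_map,
    evaluate_pose,
    filter_clashes,
    filter_peptide_bonds,
    filter_ramachandran,
    run_cascade,
)
from pepscreen.structio import Pose, Structure, annotate
from pepscreen.synth import build_peptide, make_pose_library

from conftest import make_atom


def make_pose(structure, score=-9.0, rank=1, compound_id="cpd"):
    return Pose(ligand=structure, score=score, rank=rank, compound_id=compound_id)


@pytest.fixture(scope="module")
def rama_map():
    return RamachandranMap.default()


class TestRamachandranMap:
    def test_default_matches_builder(self, rama_map):
        built = build_default_map()
        for cls in ("general", "glycine", "proline"):
            np.testing.assert_array_equal(rama_map.masks[cls], built.masks[cls])

    def test_every_class_has_allowed_bins(self, rama_map):
        for cls, mask in rama_map.masks.items():
            assert mask.any()

    def test_bin_index_tiles_domain(self, rama_map):
        assert rama_map.bin_index(-180.0 + 1e-9) == 0
        assert rama_map.bin_index(180.0) == rama_map.n_bins - 1
        assert rama_map.bin_index(-175.0) == 0
        assert rama_map.bin_index(-170.0) == 0  # upper edge belongs to the bin
        assert rama_map.bin_index(-169.9) == 1

    def test_helical_region_allowed_all_classes(self, rama_map):
        assert rama_map.allowed(-60, -45, "general")
        assert rama_map.allowed(-60, -45, "glycine")
        assert rama_map.allowed(-60, -45, "proline")

    def test_disallowed_bin_direct_grid_indexing(self, rama_map):
        phi, psi = 75.0, -60.0
        pi, qi = rama_map.bin_index(phi), rama_map.bin_index(psi)
        assert not rama_map.masks["general"][pi, qi]
        assert not rama_map.allowed(phi, psi, "general")

    def test_glycine_mirror_symmetry(self, rama_map):
        g = rama_map.masks["glycine"]
        np.testing.assert_array_equal(g, g[::-1, ::-1])

    def test_residue_class(self):
        assert RamachandranMap.residue_class("GLY") == "glycine"
        assert RamachandranMap.residue_class("PRO") == "proline"
        assert RamachandranMap.residue_class("ALA") == "general"
        assert RamachandranMap.residue_class("XYZ", has_cbeta=False) == "glycine"


class TestFilterRamachandran:
    def test_helical_peptide_passes(self, rama_map, helical_peptide):
        verdict = filter_ramachandran(make_pose(helical_peptide), rama_map)
        assert verdict.passed

    def test_forced_disallowed_residue_flagged(self, rama_map):
        torsions = [(-60.0, -45.0, 180.0)] * 5
        torsions[2] = (75.0, -60.0, 180.0)
        s = build_peptide("AAAAA", torsions)
        verdict = filter_ramachandran(make_pose(s), rama_map)
        assert not verdict.passed
        assert [f[1] for f in verdict.failures] == [3]

    def test_glycine_tolerates_mirrored_region(self, rama_map):
        torsions = [(-60.0, -45.0, 180.0)] * 5
        torsions[2] = (120.0, -130.0, 180.0)  # mirrored beta: fine for Gly only
        gly = build_peptide("AAGAA", torsions)
        assert filter_ramachandran(make_pose(gly), rama_map).passed
        ala = build_peptide("AAAAA", torsions)
        assert not filter_ramachandran(make_pose(ala), rama_map).passed

    def test_single_residue_vacuous_pass(self, rama_map):
        s = build_peptide("A", [(-60.0, -45.0, 180.0)])
        assert filter_ramachandran(make_pose(s), rama_map).passed

    def test_no_backbone_raises_distinct_error(self, rama_map):
        s = annotate(Structure(atoms=[make_atom(name="C1", element="C")]))
        with pytest.raises(BackboneError):
            filter_ramachandran(make_pose(s), rama_map)


class TestFilterPeptideBonds:
    def test_all_trans_passes(self, helical_peptide):
        assert filter_peptide_bonds(make_pose(helical_peptide)).passed

    def test_cis_bond_labeled(self):
        torsions = [(-120.0, 130.0, 180.0)] * 4
        torsions[1] = (-120.0, 130.0, 0.0)
        s = build_peptide("AAAA", torsions)
        verdict = filter_peptide_bonds(make_pose(s))
        assert not verdict.passed
        assert verdict.failures[0][4] == "cis"
        assert verdict.failures[0][1] == 2

    def test_nonplanar_bond_labeled(self):
        torsions = [(-120.0, 130.0, 180.0)] * 4
        torsions[2] = (-120.0, 130.0, 100.0)  # 30 < 100 < 150
        s = build_peptide("AAAA", torsions)
        verdict = filter_peptide_bonds(make_pose(s))
        assert not verdict.passed
        assert verdict.failures[0][4] == "non-planar"

    def test_missing_omega_atoms_warn_not_fail(self):
        s = build_peptide("AAA", [(-120.0, 130.0, 180.0)] * 3)
        pruned = Structure([a for a in s.atoms if not (a.residue_seq == 3 and a.name == "CA")])
        with pytest.warns(UserWarning, match="omega undefined"):
            verdict = filter_peptide_bonds(make_pose(pruned))
        assert verdict.passed

    def test_threshold_boundaries(self):
        config = FilterConfig()
        for omega, ok in [(150.0, True), (149.9, False), (30.0, False), (-180.0, True)]:
            torsions = [(-120.0, 130.0, 180.0)] * 3
            torsions[0] = (-120.0, 130.0, omega)
            s = build_peptide("AAA", torsions)
            assert filter_peptide_bonds(make_pose(s), config).passed is ok


class TestFilterClashes:
    def test_ideal_peptide_passes(self, helical_peptide):
        assert filter_clashes(make_pose(helical_peptide)).passed

    def test_displaced_sidechain_reported(self):
        s = build_peptide("AAAAA", [(-120.0, 130.0, 180.0)] * 5)
        coords = s.coords()
        atoms = s.atoms
        cb2 = next(i for i, a in enumerate(atoms) if a.residue_seq == 2 and a.name == "CB")
        c5 = next(i for i, a in enumerate(atoms) if a.residue_seq == 5 and a.name == "C")
        coords[cb2] = coords[c5] + np.array([1.0, 0.0, 0.0])
        verdict = filter_clashes(make_pose(s.with_coords(coords)))
        assert not verdict.passed
        labels = {f[0] for f in verdict.failures} | {f[1] for f in verdict.failures}
        assert "ALA2:CB" in labels and "ALA5:C" in labels

    def test_bonded_neighbors_exempt(self, helical_peptide):
        # N-CA at ~1.46 A would be a monstrous "clash" if bonds were not exempt
        verdict = filter_clashes(make_pose(helical_peptide))
        assert verdict.passed

    def test_matches_brute_force_on_decoys(self, rng):
        config = FilterConfig()
        library, labels = make_pose_library(
            10, 5, {"clash": 0.5}, seed=11
        )
        from pepscreen.posefilter import _bond_adjacency
        from collections import deque

        for cid, poses in library.items():
            for pose, info in zip(poses, labels.truth["poses"][cid]):
                heavy = [a for a in pose.ligand.atoms if not a.is_hydrogen]
                adj = _bond_adjacency(heavy)
                # brute-force all-pairs check
                def sep(i, j):
                    dist = {i: 0}
                    q = deque([i])
                    while q:
                        u = q.popleft()
                        for v in adj[u]:
                            if v not in dist:
                                dist[v] = dist[u] + 1
                                q.append(v)
                    return dist.get(j, 10**9)

                expect_fail = False
                for i in range(len(heavy)):
                    for j in range(i + 1, len(heavy)):
                        if sep(i, j) < config.min_bond_separation:
                            continue
                        d = np.linalg.norm(heavy[i].position - heavy[j].position)
                        if d < heavy[i].vdw_radius + heavy[j].vdw_radius - config.clash_overlap:
                            expect_fail = True
                got = filter_clashes(pose, config)
                assert got.passed == (not expect_fail)
                assert (not got.passed) == info["defects"]["clash"]


class TestEnergyCut:
    def test_boundary_kept(self):
        lig = build_peptide("AA", [(-60, -45, 180)] * 2)
        poses = [make_pose(lig, score=s, rank=i + 1) for i, s in enumerate([-10.2, -8.0, -7.9])]
        kept = apply_energy_cut(poses)
        assert [p.score for p in kept] == [-10.2, -8.0]

    def test_empty_set(self):
        assert apply_energy_cut([]) == []

    def test_all_above_cut(self):
        lig = build_peptide("AA", [(-60, -45, 180)] * 2)
        poses = [make_pose(lig, score=-7.0), make_pose(lig, score=-5.0, rank=2)]
        assert apply_energy_cut(poses) == []


class TestRunCascade:
    def test_single_perfect_pose(self):
        lig = build_peptide("AAAAA", [(-60.0, -45.0, 180.0)] * 5)
        report = run_cascade({"cpd": [make_pose(lig, score=-9.0)]})
        assert len(report.survivors) == 1
        assert report.stage_counts["pass_energy"] == 1

    def test_survivors_equal_filter_intersection(self):
        library, labels = make_pose_library(
            15, 8, {"ramachandran": 0.25, "omega": 0.25, "clash": 0.25}, seed=5
        )
        config = FilterConfig()
        report = run_cascade(library, config=config)
        expected = set()
        for cid, infos in labels.truth["poses"].items():
            for info in infos:
                defects = info["defects"]
                if not any(defects.values()) and info["score"] <= config.energy_cutoff:
                    expected.add((cid, info["rank"]))
        got = {(p.compound_id, p.rank) for p in report.survivors}
        assert got == expected

    def test_stage_counts_monotone(self):
        library, _ = make_pose_library(10, 6, {"ramachandran": 0.3, "omega": 0.3, "clash": 0.3}, seed=9)
        counts = run_cascade(library).stage_counts
        order = ["considered", "pass_ramachandran", "pass_peptide_bonds", "pass_clashes", "pass_energy"]
        values = [counts[k] for k in order]
        assert values == sorted(values, reverse=True)

    def test_all_poses_failing_compound_absent(self):
        library, _ = make_pose_library(3, 4, {"ramachandran": 1.0}, seed=2)
        report = run_cascade(library)
        assert report.survivors == []
        assert report.per_compound_best == {}

    def test_merged_sorted_and_deterministic(self):
        library, _ = make_pose_library(8, 6, {"clash": 0.3}, seed=4)
        r1 = run_cascade(library)
        r2 = run_cascade(library)
        scores = [p.score for p in r1.survivors]
        assert scores == sorted(scores)
        assert [(p.compound_id, p.rank) for p in r1.survivors] == [
            (p.compound_id, p.rank) for p in r2.survivors
        ]

    def test_top_n_restriction(self):
        library, _ = make_pose_library(2, 10, seed=8, score_distribution=(-9.0, 0.5))
        report = run_cascade(library, config=FilterConfig(top_n_poses=3))
        assert report.stage_counts["considered"] == 6

    def test_empty_library_raises(self):
        with pytest.raises(ValueError):
            run_cascade({})

    def test_widening_tolerances_never_shrinks_survivors(self):
        library, _ = make_pose_library(10, 5, {"omega": 0.4, "clash": 0.3}, seed=13)
        base = run_cascade(library, config=FilterConfig())
        loose = run_cascade(
            library,
            config=FilterConfig(
                omega_trans_min=120.0, clash_overlap=0.8, energy_cutoff=-6.0
            ),
        )
        assert {(p.compound_id, p.rank) for p in base.survivors} <= {
            (p.compound_id, p.rank) for p in loose.survivors
        }
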