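"""Descriptor oracles: hand geometry, brute-force formulas, dense SASA
sampling, constructed hydrogen-bond accept/reject cases."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import grid_topology, make_atom, make_ensemble

from ensdiff.descriptors import (
    hbond_count,
    hbond_frequency_table,
    radius_of_gyration,
    region_distance,
    rmsf,
    rmsf_series,
    sasa,
)
from ensdiff.ensemble import (
    Component,
    RegionDefinition,
    Topology,
    strip_component,
)
from ensdiff.errors import (
    AnnotationError,
    EmptyRegionError,
    FitError,
    InsufficientDataError,
)


def two_region_topology(masses_a, masses_b):
    atoms = []
    i = 0
    for m in masses_a:
        atoms.append(make_atom(i, resseq=1, mass=m))
        i += 1
    for m in masses_b:
        atoms.append(make_atom(i, resseq=2, mass=m))
        i += 1
    return Topology(atoms)


REG1 = RegionDefinition("r1", "A", 1, 1)
REG2 = RegionDefinition("r2", "A", 2, 2)


class TestRegionDistance:
    def test_same_region_is_zero(self):
        top = two_region_topology([1.0, 1.0], [1.0])
        xyz = np.random.default_rng(0).normal(size=(1, 3, 3))
        ens = make_ensemble(top, [xyz])
        d = region_distance(ens, REG1, REG1)
        assert np.allclose(d.pooled(), 0.0)

    def test_three_four_five_triangle(self):
        top = two_region_topology([1.0], [1.0])
        xyz = np.array([[[0.0, 0, 0], [3.0, 4.0, 0]]])
        ens = make_ensemble(top, [xyz])
        assert region_distance(ens, REG1, REG2).pooled()[0] == pytest.approx(
            5.0
        )

    def test_mass_weighted_centroids_match_hand_arithmetic(self):
        # region 1: masses 1 and 3 at x=0 and x=4 -> centroid x=3
        # region 2: masses 2 and 2 at (10,1,0),(10,-1,0) -> centroid (10,0,0)
        top = two_region_topology([1.0, 3.0], [2.0, 2.0])
        xyz = np.array(
            [[[0.0, 0, 0], [4.0, 0, 0], [10.0, 1, 0], [10.0, -1, 0]]]
        )
        ens = make_ensemble(top, [xyz])
        assert region_distance(ens, REG1, REG2).pooled()[0] == pytest.approx(
            7.0, abs=1e-12
        )

    def test_empty_region_raises(self):
        top = two_region_topology([1.0], [1.0])
        ens = make_ensemble(top, [np.zeros((1, 2, 3))])
        with pytest.raises(EmptyRegionError):
            region_distance(ens, RegionDefinition("x", "A", 9, 9), REG2)


class TestRadiusOfGyration:
    def test_single_atom_zero(self):
        top = two_region_topology([12.0], [1.0])
        ens = make_ensemble(top, [np.zeros((2, 2, 3))])
        assert np.allclose(radius_of_gyration(ens, REG1).pooled(), 0.0)

    def test_two_unit_masses_two_angstrom_apart(self):
        top = two_region_topology([1.0, 1.0], [1.0])
        xyz = np.array([[[0.0, 0, 0], [2.0, 0, 0], [9.0, 0, 0]]])
        ens = make_ensemble(top, [xyz])
        assert radius_of_gyration(ens, REG1).pooled()[0] == pytest.approx(
            1.0, abs=1e-12
        )

    def test_asymmetric_masses_match_direct_formula(self):
        rng = np.random.default_rng(3)
        masses = [1.0, 2.5, 7.0, 0.5]
        top = two_region_topology(masses, [1.0])
        pts = rng.normal(size=(5, 3))
        frames = pts[None]
        ens = make_ensemble(top, [frames])
        got = radius_of_gyration(ens, REG1).pooled()[0]
        m = np.array(masses)
        r = pts[:4]
        com = (r * m[:, None]).sum(0) / m.sum()
        expected = np.sqrt((m * ((r - com) ** 2).sum(1)).sum() / m.sum())
        assert got == pytest.approx(expected, abs=1e-9)


def rmsf_fixture(mover):
    """5 fixed anchor atoms + one CA that follows ``mover[frame]``."""
    atoms = [
        make_atom(0, name="C0", resseq=1),
        make_atom(1, name="C1", resseq=1),
        make_atom(2, name="C2", resseq=1),
        make_atom(3, name="C3", resseq=1),
        make_atom(4, name="CA", resseq=1),
        make_atom(5, name="CA", resseq=2),
    ]
    top = Topology(atoms)
    anchors = np.array(
        [[0, 0, 0], [4, 0, 0], [0, 4, 0], [0, 0, 4], [1.5, 1.5, 0.0]]
    )
    frames = []
    for pos in mover:
        frames.append(np.vstack([anchors, np.asarray(pos)[None]]))
    return top, np.array(frames)


FIT = RegionDefinition("fit", "A", 1, 1)
TARGET = RegionDefinition("target", "A", 2, 2)


class TestRmsf:
    def test_static_trajectory_is_zero(self):
        top, frames = rmsf_fixture([[8, 0, 0]] * 4)
        ens = make_ensemble(top, [frames])
        mapping, mean = rmsf(ens, FIT, TARGET)
        assert mean == pytest.approx(0.0, abs=1e-12)

    def test_alternating_atom_has_unit_rmsf(self):
        top, frames = rmsf_fixture([[1, 0, 0], [-1, 0, 0]] * 3)
        ens = make_ensemble(top, [frames])
        mapping, mean = rmsf(ens, FIT, TARGET)
        assert mean == pytest.approx(1.0, abs=1e-9)
        assert mapping[("A", 2, "")] == pytest.approx(1.0, abs=1e-9)

    def test_rigid_rotations_removed_by_superposition(self):
        top, frames = rmsf_fixture([[8, 0, 0]] * 5)
        rng = np.random.default_rng(4)
        rotated = []
        for k, frame in enumerate(frames):
            r = Rotation.random(random_state=int(rng.integers(1 << 16)))
            rotated.append(frame @ r.as_matrix().T + rng.normal(size=3))
        ens = make_ensemble(top, [np.array(rotated)])
        _, mean = rmsf(ens, FIT, TARGET)
        assert mean == pytest.approx(0.0, abs=1e-9)

    def test_too_few_frames_raises(self):
        top, frames = rmsf_fixture([[8, 0, 0]])
        ens = make_ensemble(top, [frames])
        with pytest.raises(InsufficientDataError):
            rmsf(ens, FIT, TARGET)

    def test_collinear_fit_region_raises(self):
        atoms = [make_atom(i, name=f"C{i}", resseq=1) for i in range(3)]
        atoms.append(make_atom(3, name="CA", resseq=2))
        top = Topology(atoms)
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [5, 5, 5.0]])
        frames = np.array([line, line + 0.1])
        ens = make_ensemble(top, [frames])
        with pytest.raises(FitError):
            rmsf(ens, FIT, TARGET)

    def test_series_matches_per_replica_mean(self, toy_system):
        bound, _, regions = toy_system
        series = rmsf_series(
            bound, [regions["stemA"], regions["stemB"]], regions["loopA"]
        )
        assert series.n_replicas == bound.n_replicas
        assert all(v.size == 1 for v in series.values)
        # replica mean of the series equals the rmsf() region mean
        _, region_mean = rmsf(
            bound, [regions["stemA"], regions["stemB"]], regions["loopA"]
        )
        assert series.replica_means().mean() == pytest.approx(
            region_mean, rel=1e-9
        )


def dense_sasa(coords, radii, region_idx, probe=1.4, n_points=8000):
    """Independent rolling-probe surface integration (golden spiral)."""
    k = np.arange(n_points)
    phi = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (k + 0.5) / n_points
    r = np.sqrt(1.0 - z * z)
    pts = np.stack([r * np.cos(k * phi), r * np.sin(k * phi), z], axis=1)
    expanded = radii + probe
    total = 0.0
    for i in region_idx:
        sphere = coords[i] + expanded[i] * pts
        exposed = np.ones(n_points, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            d = np.linalg.norm(sphere - coords[j], axis=1)
            exposed &= d > expanded[j]
        total += 4 * np.pi * expanded[i] ** 2 * exposed.mean()
    return total


def sasa_fixture(coords, radii):
    atoms = [
        make_atom(i, resseq=1, vdw=radii[i]) for i in range(len(coords))
    ]
    top = Topology(atoms)
    ens = make_ensemble(top, [np.asarray(coords, dtype=float)[None]])
    return ens


WHOLE = RegionDefinition("whole", "A", 1, 1)


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        r = 1.7
        ens = sasa_fixture([[0, 0, 0]], [r])
        got = sasa(ens, WHOLE).pooled()[0]
        assert got == pytest.approx(4 * np.pi * (r + 1.4) ** 2, rel=1e-3)

    def test_buried_atom_is_zero(self):
        # central atom caged by 26 overlapping neighbours on a 3x3x3 grid
        offsets = [
            (x, y, z)
            for x in (-2.0, 0, 2.0)
            for y in (-2.0, 0, 2.0)
            for z in (-2.0, 0, 2.0)
        ]
        coords = [(0.0, 0, 0)] + [o for o in offsets if o != (0.0, 0, 0)]
        atoms = [make_atom(0, resseq=1, vdw=1.7)] + [
            make_atom(i + 1, resseq=2, vdw=2.2)
            for i in range(len(coords) - 1)
        ]
        top = Topology(atoms)
        ens = make_ensemble(top, [np.asarray(coords)[None]])
        got = sasa(ens, WHOLE).pooled()[0]
        assert got == pytest.approx(0.0, abs=1e-6)

    def test_overlapping_spheres_match_dense_oracle(self):
        coords = np.array([[0.0, 0, 0], [2.4, 0.3, -0.2], [4.0, -1.0, 0.8]])
        radii = np.array([1.7, 1.52, 1.55])
        ens = sasa_fixture(coords, radii)
        got = sasa(ens, WHOLE).pooled()[0]
        expected = dense_sasa(coords, radii, range(3))
        assert got == pytest.approx(expected, rel=0.02)

    def test_stripped_context_never_smaller(self, toy_system):
        bound, _, regions = toy_system
        small = bound.subset_frames(slice(0, 3))
        full = sasa(small, regions["loopA"]).pooled()
        stripped = sasa(
            small,
            regions["loopA"],
            context=("receptor_alpha", "receptor_beta"),
        ).pooled()
        assert np.all(stripped >= full - 1e-9)
        assert stripped.mean() > full.mean()

    def test_region_must_be_receptor(self, toy_system):
        bound, _, _ = toy_system
        with pytest.raises(EmptyRegionError):
            sasa(bound.subset_frames(slice(0, 1)),
                 RegionDefinition("lig", "M", 1, 5))


def hbond_fixture(acceptor_pos, h_pos=(1.0, 0.0, 0.0)):
    """Donor O at origin with H, acceptor O of the other chain."""
    atoms = [
        make_atom(0, name="O1", element="O", resseq=1, chain="A",
                  donor=True, acceptor=True, mass=15.999),
        make_atom(1, name="H1", element="H", resseq=1, chain="A",
                  polar_h=True, mass=1.008),
        make_atom(2, name="O2", element="O", resseq=1, chain="B",
                  component=Component.RECEPTOR_BETA,
                  acceptor=True, mass=15.999),
    ]
    top = Topology(atoms)
    frame = np.array([[0.0, 0, 0], list(h_pos), list(acceptor_pos)])
    ens = make_ensemble(top, [frame[None]])
    return ens


SEL_A = np.array([0, 1])
SEL_B = np.array([2])


class TestHbonds:
    def test_ideal_geometry_accepted(self):
        ens = hbond_fixture([2.9, 0, 0])  # D-A 2.9 Å, H-D-A angle 0°
        assert hbond_count(ens, SEL_A, SEL_B).pooled()[0] == 1

    def test_wide_angle_rejected(self):
        # acceptor at 45° from the D-H direction, distance 2.9 Å
        a = 2.9 / np.sqrt(2)
        ens = hbond_fixture([a, a, 0])
        assert hbond_count(ens, SEL_A, SEL_B).pooled()[0] == 0

    def test_long_distance_rejected(self):
        ens = hbond_fixture([3.6, 0, 0])
        assert hbond_count(ens, SEL_A, SEL_B).pooled()[0] == 0

    def test_boundary_distance_accepted(self):
        ens = hbond_fixture([3.5, 0, 0])
        assert hbond_count(ens, SEL_A, SEL_B).pooled()[0] == 1

    def test_empty_selection_counts_zero(self):
        ens = hbond_fixture([2.9, 0, 0])
        counts = hbond_count(ens, np.array([], dtype=int), SEL_B)
        assert np.all(counts.pooled() == 0)

    def test_overlapping_selections_rejected(self):
        ens = hbond_fixture([2.9, 0, 0])
        with pytest.raises(ValueError):
            hbond_count(ens, SEL_A, np.array([1, 2]))

    def test_missing_annotations_raise(self):
        atoms = [
            make_atom(0, name="C1", resseq=1, chain="A"),
            make_atom(1, name="C2", resseq=1, chain="B",
                      component=Component.RECEPTOR_BETA),
        ]
        ens = make_ensemble(Topology(atoms),
                            [np.zeros((1, 2, 3)) + [[0, 0, 0], [3, 0, 0]]])
        with pytest.raises(AnnotationError):
            hbond_count(ens, np.array([0]), np.array([1]))

    def test_frequency_fraction_and_sparsity(self):
        # bond present in 5 of 10 frames; a second pair never forms
        frames = []
        for f in range(10):
            x = 2.9 if f < 5 else 5.0
            frames.append([[0.0, 0, 0], [1.0, 0, 0], [x, 0, 0]])
        atoms = [
            make_atom(0, name="O1", element="O", resseq=1, chain="A",
                      donor=True, acceptor=True, mass=15.999),
            make_atom(1, name="H1", element="H", resseq=1, chain="A",
                      polar_h=True, mass=1.008),
            make_atom(2, name="O2", element="O", resseq=1, chain="B",
                      component=Component.RECEPTOR_BETA, acceptor=True,
                      mass=15.999),
        ]
        ens = make_ensemble(Topology(atoms), [np.array(frames)])
        table = hbond_frequency_table(ens, SEL_A, SEL_B)
        assert table.frequencies == {(0, 2): 0.5}
        assert table.total_frames == 10

    def test_bernoulli_occupancy_concentrates(self):
        from ensdiff.synthetic import ToyEnsembleSpec, generate_toy_ensemble

        spec = ToyEnsembleSpec(seed=21, n_replicas=1, n_frames=2000,
                               hbond_p_bound=0.3, ligand_attached=False)
        bound, _, regions = generate_toy_ensemble(spec)
        top = bound.topology
        mid = (regions["loopA"].start_residue
               + regions["loopA"].end_residue) // 2
        donor = int(np.nonzero((top.chain_ids == "A")
                               & (top.residue_seqs == mid)
                               & (top.atom_names == "N"))[0][0])
        acceptor = int(np.nonzero((top.chain_ids == "B")
                                  & (top.residue_seqs == mid)
                                  & (top.atom_names == "O"))[0][0])
        sel_a = np.nonzero(top.components == "receptor_alpha")[0]
        sel_b = np.nonzero(top.components == "receptor_beta")[0]
        table = hbond_frequency_table(bound, sel_a, sel_b)
        assert table.frequencies[(donor, acceptor)] == pytest.approx(
            0.30, abs=0.03
        )

    def test_count_consistent_with_frequency_table(self, toy_system):
        bound, _, _ = toy_system
        top = bound.topology
        sel_a = np.nonzero(top.components == "receptor_alpha")[0]
        sel_b = np.nonzero(top.components == "receptor_beta")[0]
        counts = hbond_count(bound, sel_a, sel_b)
        table = hbond_frequency_table(bound, sel_a, sel_b)
        total_from_counts = counts.pooled().sum()
        total_from_table = sum(table.frequencies.values()) * (
            table.total_frames
        )
        assert total_from_counts == pytest.approx(total_from_table)


class TestRigidBodyInvariance:
    def test_descriptors_invariant_under_global_motion(self, toy_system):
        bound, _, regions = toy_system
        small = bound.subset_frames(slice(0, 4))
        small.coordinates = small.coordinates[:2]
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        shift = np.array([5.0, -3.0, 12.0])
        moved = make_ensemble(
            small.topology,
            [xyz @ rot.T + shift for xyz in small.coordinates],
        )
        d0 = region_distance(small, regions["loopA"],
                             regions["loopB"]).pooled()
        d1 = region_distance(moved, regions["loopA"],
                             regions["loopB"]).pooled()
        assert np.allclose(d0, d1, atol=1e-9)
        g0 = radius_of_gyration(small, regions["loopA"]).pooled()
        g1 = radius_of_gyration(moved, regions["loopA"]).pooled()
        assert np.allclose(g0, g1, atol=1e-9)
        fit = [regions["stemA"], regions["stemB"]]
        r0 = rmsf_series(small, fit, regions["loopA"]).pooled()
        r1 = rmsf_series(moved, fit, regions["loopA"]).pooled()
        assert np.allclose(r0, r1, atol=1e-9)
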