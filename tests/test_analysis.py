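"""RMSD, Rg, clustering, reaction coordinates, Ramachandran populations,
and Karplus couplings."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.spatial.transform import Rotation

from torsionfold.analysis import (
    KarplusParams,
    NativeContactSpec,
    RamaClassifier,
    classify_conformations,
    collective_hbond_distance,
    kabsch_rmsd,
    karplus_j,
    kmeans_cluster,
    radius_of_gyration,
    stacking_distance,
)
from torsionfold.constants import KB_KCAL_MOL_K, STRICT_RAMA_REGIONS
from torsionfold.peptide import PeptideStructure, Trajectory, build_ideal_peptide
from torsionfold.sampling import McConfig, metropolis_mc
from torsionfold.torsion2d import FourierCoefficients


def jittered(base, n, sigma, rng):
    return [base.with_coordinates(
        base.coordinates + rng.normal(scale=sigma,
                                      size=base.coordinates.shape))
        for _ in range(n)]


class TestKabschRmsd:
    def test_self_rmsd_is_zero(self, helix12):
        assert kabsch_rmsd(helix12, helix12) < 1e-12

    def test_rigid_transform_is_recovered(self, helix12, rng):
        rot = Rotation.from_rotvec(
            np.radians(37.0) * np.array([0.36, 0.48, 0.8])).as_matrix()
        moved = helix12.with_coordinates(
            helix12.coordinates @ rot.T + np.array([3.0, -7.0, 11.0]))
        assert kabsch_rmsd(moved, helix12) < 1e-10

    def test_fitted_rmsd_never_exceeds_raw(self, helix12, extended12):
        raw = np.sqrt(np.mean(np.sum(
            (helix12.coordinates - extended12.coordinates) ** 2, axis=1)))
        assert kabsch_rmsd(helix12, extended12) <= raw

    def test_symmetry(self, helix12, extended12):
        a = kabsch_rmsd(helix12, extended12)
        b = kabsch_rmsd(extended12, helix12)
        assert a == pytest.approx(b, abs=1e-10)

    def test_mismatched_selections_rejected(self, helix12, trpzip_like):
        with pytest.raises(ValueError, match="length"):
            kabsch_rmsd(helix12, trpzip_like)

    def test_matches_scipy_align_vectors(self, helix12, rng):
        """Independent oracle: scipy's Kabsch implementation."""
        other = helix12.with_coordinates(
            helix12.coordinates + rng.normal(scale=0.5,
                                             size=helix12.coordinates.shape))
        a = other.coordinates - other.coordinates.mean(axis=0)
        b = helix12.coordinates - helix12.coordinates.mean(axis=0)
        rot, rssd = Rotation.align_vectors(b, a)
        want = rssd / np.sqrt(len(a))
        assert kabsch_rmsd(other, helix12) == pytest.approx(want, abs=1e-8)


class TestRadiusOfGyration:
    def test_single_atom_is_zero(self):
        s = PeptideStructure(atom_names=["CA"], residue_names=["ALA"],
                             residue_indices=[1], elements=["C"],
                             coordinates=[[1.0, 2.0, 3.0]])
        assert radius_of_gyration(s) == 0.0

    def test_symmetric_pair(self):
        s = PeptideStructure(
            atom_names=["CA", "CA"], residue_names=["ALA", "ALA"],
            residue_indices=[1, 2], elements=["C", "C"],
            coordinates=[[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        assert radius_of_gyration(s) == pytest.approx(1.0)

    def test_matches_double_loop_oracle(self, rng):
        coords = rng.normal(size=(50, 3)) * 5
        s = PeptideStructure(
            atom_names=["CA"] * 50, residue_names=["ALA"] * 50,
            residue_indices=np.arange(1, 51), elements=["C"] * 50,
            coordinates=coords)
        cm = coords.mean(axis=0)
        acc = 0.0
        for r in coords:
            acc += np.dot(r - cm, r - cm)
        assert radius_of_gyration(s) == pytest.approx(
            np.sqrt(acc / 50), abs=1e-12)

    def test_empty_selection_rejected(self, helix12):
        with pytest.raises(ValueError, match="empty"):
            radius_of_gyration(helix12, atom_selection=[])


class TestKmeansCluster:
    def test_two_clump_fixture_is_perfectly_separated(self, helix12,
                                                      extended12, rng):
        ext_like = helix12.with_coordinates(extended12.coordinates)
        frames = (jittered(helix12, 10, 0.1, rng)
                  + jittered(ext_like, 10, 0.1, rng))
        traj = Trajectory(frames=frames)
        labels, centroids, pops = kmeans_cluster(traj, 2, seed=3)
        assert set(labels[:10]) != set(labels[10:])
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        np.testing.assert_allclose(sorted(pops), [0.5, 0.5])
        assert pops.sum() == 1.0

    def test_matches_sklearn_partition(self, helix12, extended12, rng):
        from sklearn.cluster import KMeans
        ext_like = helix12.with_coordinates(extended12.coordinates)
        frames = (jittered(helix12, 8, 0.2, rng)
                  + jittered(ext_like, 8, 0.2, rng))
        traj = Trajectory(frames=frames)
        labels, _, _ = kmeans_cluster(traj, 2, seed=0)
        from torsionfold.analysis import _featurize
        x = _featurize(traj, None)
        ref = KMeans(n_clusters=2, n_init=10, random_state=0).fit_predict(x)
        # same partition up to label permutation
        agreement = max(np.mean(labels == ref), np.mean(labels != ref))
        assert agreement == 1.0

    def test_k_equals_one(self, helix12, rng):
        traj = Trajectory(frames=jittered(helix12, 5, 0.1, rng))
        labels, centroids, pops = kmeans_cluster(traj, 1, seed=0)
        assert set(labels) == {0} and pops[0] == 1.0

    def test_duplicate_frames_have_zero_inertia(self, helix12):
        traj = Trajectory(frames=[helix12] * 6)
        labels, centroids, pops = kmeans_cluster(traj, 2, seed=0)
        from torsionfold.analysis import _featurize
        x = _featurize(traj, None)
        for c in np.unique(labels):
            member = x[labels == c]
            assert ((member - member.mean(axis=0)) ** 2).sum() < 1e-16

    def test_k_exceeding_frames_rejected(self, helix12):
        with pytest.raises(ValueError):
            kmeans_cluster(Trajectory(frames=[helix12] * 3), 4)

    def test_seeded_runs_are_deterministic(self, helix12, rng):
        traj = Trajectory(frames=jittered(helix12, 12, 0.3, rng))
        a = kmeans_cluster(traj, 3, seed=11)
        b = kmeans_cluster(traj, 3, seed=11)
        assert np.array_equal(a[0], b[0]) and a[1] == b[1]


HAIRPIN_SPEC = NativeContactSpec(
    hbond_pairs=((2, 11), (4, 9), (9, 4), (11, 2)),
    stacking_pairs=((2, 11), (4, 9)),
)


class TestReactionCoordinates:
    def test_constant_distances(self, trpzip_like):
        spec = NativeContactSpec(hbond_pairs=((1, 12),))
        d = collective_hbond_distance(trpzip_like, spec)
        n = trpzip_like.position(1, "N")
        o = trpzip_like.position(12, "O")
        assert d == pytest.approx(np.linalg.norm(n - o))

    def test_mean_aggregation(self):
        # synthetic 4-residue frame with controlled N/O placements
        names, rnames, rids, elems, xyz = [], [], [], [], []
        targets = [2.8, 3.0, 3.2, 3.0]
        for i, t in enumerate(targets):
            for nm, el, pos in (("N", "N", [10.0 * i, 0, 0]),
                                ("CA", "C", [10.0 * i, 1, 0]),
                                ("C", "C", [10.0 * i, 2, 0]),
                                ("O", "O", [10.0 * i + t, 0, 0])):
                names.append(nm)
                rnames.append("ALA")
                rids.append(i + 1)
                elems.append(el)
                xyz.append(pos)
        s = PeptideStructure(atom_names=names, residue_names=rnames,
                             residue_indices=rids, elements=elems,
                             coordinates=xyz)
        spec = NativeContactSpec(hbond_pairs=tuple((i, i) for i in (1, 2, 3, 4)))
        assert collective_hbond_distance(s, spec) == pytest.approx(3.0)
        assert collective_hbond_distance(s, spec, mode="max") == pytest.approx(3.2)

    def test_helix_is_farther_than_hairpin_on_hairpin_spec(self, trpzip_like):
        helix = build_ideal_peptide("SWTWENGKWTWK", [(-57.0, -47.0)] * 12)
        d_hairpin = collective_hbond_distance(trpzip_like, HAIRPIN_SPEC)
        d_helix = collective_hbond_distance(helix, HAIRPIN_SPEC)
        assert np.isfinite(d_helix)
        assert d_helix > d_hairpin

    def test_stacking_mean(self, trpzip_like):
        l_val = stacking_distance(trpzip_like, HAIRPIN_SPEC)
        from torsionfold.analysis import _trp_centroid
        d1 = np.linalg.norm(_trp_centroid(trpzip_like, 2)
                            - _trp_centroid(trpzip_like, 11))
        d2 = np.linalg.norm(_trp_centroid(trpzip_like, 4)
                            - _trp_centroid(trpzip_like, 9))
        assert l_val == pytest.approx((d1 + d2) / 2)

    def test_hairpin_stacks_tighter_than_extended(self, trpzip_like):
        from conftest import HAIRPIN_ANGLES  # noqa: F401
        extended = build_ideal_peptide("SWTWENGKWTWK", [(180.0, 180.0)] * 12)
        assert (stacking_distance(trpzip_like, HAIRPIN_SPEC)
                < stacking_distance(extended, HAIRPIN_SPEC))

    def test_non_trp_stacking_residue_rejected(self, trpzip_like):
        spec = NativeContactSpec(hbond_pairs=((2, 11),),
                                 stacking_pairs=((1, 11),))
        with pytest.raises(ValueError, match="not TRP"):
            stacking_distance(trpzip_like, spec)

    def test_internal_coordinates_are_rigid_invariant(self, trpzip_like, rng):
        rot = Rotation.random(random_state=5).as_matrix()
        moved = trpzip_like.with_coordinates(
            trpzip_like.coordinates @ rot.T + rng.normal(size=3) * 20)
        assert collective_hbond_distance(moved, HAIRPIN_SPEC) == pytest.approx(
            collective_hbond_distance(trpzip_like, HAIRPIN_SPEC), abs=1e-10)
        assert stacking_distance(moved, HAIRPIN_SPEC) == pytest.approx(
            stacking_distance(trpzip_like, HAIRPIN_SPEC), abs=1e-10)


class TestRamachandranClassification:
    def test_helix_point_is_alpha_under_defaults(self):
        fractions = classify_conformations([(-57.0, -47.0)] * 100)
        assert fractions["alpha"] == 1.0

    def test_strict_regions_split_the_helix_point(self):
        strict = RamaClassifier(STRICT_RAMA_REGIONS)
        assert strict.classify(-57.0, -47.0) == "alpha_strict"
        assert strict.classify(-95.0, -10.0) == "alpha"

    def test_empty_region_list_maps_everything_to_other(self):
        fractions = classify_conformations([(0.0, 0.0), (100.0, -100.0)],
                                           RamaClassifier(regions=()))
        assert fractions == {"other": 1.0}

    def test_fractions_partition_unity(self, rng):
        pts = rng.uniform(-180, 180, size=(1000, 2))
        fractions = classify_conformations([tuple(p) for p in pts])
        assert sum(fractions.values()) == 1.0

    def test_first_match_wins_in_overlaps(self):
        # ppii and beta rectangles overlap on phi in [-110, -90]
        assert RamaClassifier().classify(-100.0, 150.0) == "ppii"


class TestKarplus:
    def test_theta_zero_gives_sum(self):
        p = KarplusParams(A=7.0, B=-1.4, C=1.6, phase_deg=60.0)
        assert karplus_j(60.0, p) == pytest.approx(7.0 - 1.4 + 1.6)

    def test_theta_ninety_gives_c(self):
        p = KarplusParams(A=7.0, B=-1.4, C=1.6, phase_deg=60.0)
        assert karplus_j(150.0, p) == pytest.approx(1.6)

    def test_two_frame_average(self):
        p = KarplusParams(A=7.0, B=-1.4, C=1.6, phase_deg=60.0)
        j = karplus_j(np.array([60.0, 150.0]), p)
        assert j.mean() == pytest.approx((7.0 - 1.4 + 2 * 1.6) / 2)


class TestClassifyKarplusPipeline:
    def test_deep_alpha_minimum_dominates_populations_and_j(self):
        """MC samples from a surface with one deep helical minimum are
        classified >90% alpha and reproduce the quadrature-averaged J."""
        # deep well centred in the default alpha box
        k, temp = 15.0, 300.0
        phi0, psi0 = -65.0, -37.0
        co = FourierCoefficients.zeros(1)
        co.c_cc[0, 0] = 2 * k
        co.c_cc[1, 0] = -k * np.cos(np.radians(phi0))
        co.c_sc[1, 0] = -k * np.sin(np.radians(phi0))
        co.c_cc[0, 1] = -k * np.cos(np.radians(psi0))
        co.c_cs[0, 1] = -k * np.sin(np.radians(psi0))
        cfg = McConfig(temperature_K=temp, n_steps=200000,
                       step_size_deg=40.0, seed=23, report_stride=2)
        chain = metropolis_mc(co, cfg, start=(phi0, psi0))
        pairs = list(zip(chain["phi"], chain["psi"]))
        fractions = classify_conformations(pairs)
        assert fractions["alpha"] > 0.9

        params = KarplusParams()
        j_mc = float(np.mean(karplus_j(chain["phi"].to_numpy(), params)))
        kt = KB_KCAL_MOL_K * temp
        boltz = lambda x: np.exp(-k * (1 - np.cos(x - np.radians(phi0))) / kt)
        z = quad(boltz, -np.pi, np.pi)[0]
        j_quad = quad(lambda x: karplus_j(np.degrees(x), params) * boltz(x),
                      -np.pi, np.pi)[0] / z
        assert abs(j_mc - j_quad) < 0.1
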