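import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from tcrmd.descriptors import (
    HBOND_ANGLE_CUTOFF_DEG,
    HBOND_DIST_CUTOFF_NM,
    VDW_RADII_NM,
    detect_hbonds,
    hbond_footprint,
    rmsf,
    sasa_frame,
    sphere_points,
)
from tcrmd.errors import AnnotationError, UndefinedFluctuationError

from conftest import make_ensemble


def brute_force_hbonds(coords, elements, donors_sel, acceptors_sel,
                       dist_cut=HBOND_DIST_CUTOFF_NM, ang_cut=HBOND_ANGLE_CUTOFF_DEG,
                       h_max=0.12):
    """Exhaustive all-triples oracle applying the two inequalities directly."""
    found = set()
    hydrogens = [i for i in range(len(elements)) if elements[i] == "H"]
    for d in donors_sel:
        if elements[d] not in ("N", "O"):
            continue
        for h in hydrogens:
            if np.linalg.norm(coords[h] - coords[d]) > h_max:
                continue
            for a in acceptors_sel:
                if elements[a] not in ("N", "O") or a == d:
                    continue
                r_da = np.linalg.norm(coords[a] - coords[d])
                if r_da > dist_cut or r_da < 1e-12:
                    continue
                v1 = coords[h] - coords[d]
                v2 = coords[a] - coords[d]
                cos = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                ang = np.degrees(np.arccos(np.clip(cos, -1, 1)))
                if ang <= ang_cut:
                    found.add((d, h, a))
    return found


class TestDetectHbonds:
    # donor N at origin with H on +x axis; acceptor O placed on +x
    ELEMENTS = np.array(["N", "H", "O"], dtype=object)

    def test_linear_bond_inside_cutoffs(self):
        coords = np.array([[0, 0, 0], [0.1, 0, 0], [0.29, 0, 0.0]])
        bonds = detect_hbonds(coords, self.ELEMENTS, [0], [2])
        assert len(bonds) == 1
        b = bonds[0]
        assert (b.donor_atom, b.hydrogen_atom, b.acceptor_atom) == (0, 1, 2)
        assert b.donor_acceptor_distance == pytest.approx(0.29)
        assert b.hda_angle == pytest.approx(0.0, abs=1e-9)

    def test_distance_beyond_cutoff(self):
        coords = np.array([[0, 0, 0], [0.1, 0, 0], [0.40, 0, 0]])
        assert detect_hbonds(coords, self.ELEMENTS, [0], [2]) == []

    def test_angle_beyond_cutoff(self):
        # acceptor at 90 degrees from the N-H direction
        coords = np.array([[0, 0, 0], [0.1, 0, 0], [0.0, 0.3, 0]])
        assert detect_hbonds(coords, self.ELEMENTS, [0], [2]) == []

    def test_donor_without_hydrogen_gives_nothing(self):
        coords = np.array([[0, 0, 0], [5.0, 0, 0], [0.29, 0, 0]])
        assert detect_hbonds(coords, self.ELEMENTS, [0], [2]) == []

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        elements = np.array(rng.choice(["N", "O", "H", "C"], size=n), dtype=object)
        coords = rng.uniform(0, 0.8, size=(n, 3))
        donors = list(range(0, n // 2))
        acceptors = list(range(n // 2, n))
        got = {(b.donor_atom, b.hydrogen_atom, b.acceptor_atom)
               for b in detect_hbonds(coords, elements, donors, acceptors)}
        want = brute_force_hbonds(coords, elements, donors, acceptors)
        assert got == want


def _two_region_system():
    """Donor residue (chain P) facing two acceptor residues (chain M)."""
    spec = [("N", "N", 1, "P"), ("H", "H", 1, "P"), ("N2", "N", 1, "P"), ("H2", "H", 1, "P"),
            ("O", "O", 1, "M"), ("O", "O", 2, "M")]
    base = np.array([
        [0.0, 0.0, 0.0], [0.1, 0.0, 0.0],      # donor 1 aimed at M:1
        [0.0, 2.0, 0.0], [0.1, 2.0, 0.0],      # donor 2 aimed at M:2
        [0.29, 0.0, 0.0], [0.29, 2.0, 0.0],
    ])
    return spec, base


class TestHbondFootprint:
    def test_persistent_bond_scores_one(self):
        spec, base = _two_region_system()
        ens = make_ensemble(spec, [base] * 4)
        fp = hbond_footprint([ens], [0, 1, 2, 3], [4, 5])
        assert fp.score("P", 1) == pytest.approx(2.0)  # two donors on residue 1
        assert fp.score("M", 1) == pytest.approx(1.0)
        assert fp.score("M", 2) == pytest.approx(1.0)

    def test_two_bonds_per_residue_exceeds_one(self):
        spec, base = _two_region_system()
        ens = make_ensemble(spec, [base] * 3)
        fp = hbond_footprint([ens], [0, 1, 2, 3], [4, 5])
        assert fp.score("P", 1) == pytest.approx(2.0)

    def test_partial_occupancy_is_count_over_frames(self):
        spec, base = _two_region_system()
        away = base.copy()
        away[4] += [1.0, 0, 0]  # break bond to M:1
        frames = [base] * 45 + [away] * 45
        ens = make_ensemble(spec, frames, times=np.arange(1, 91, dtype=float))
        fp = hbond_footprint([ens], [0, 1, 2, 3], [4, 5])
        assert fp.score("M", 1) == pytest.approx(0.5)
        assert fp.score("M", 2) == pytest.approx(1.0)

    def test_doubling_ensembles_leaves_scores_unchanged(self):
        spec, base = _two_region_system()
        away = base.copy()
        away[4] += [1.0, 0, 0]
        ens = make_ensemble(spec, [base, base, away])
        single = hbond_footprint([ens], [0, 1, 2, 3], [4, 5])
        doubled = hbond_footprint([ens, ens], [0, 1, 2, 3], [4, 5])
        assert single.scores == doubled.scores

    def test_empty_selection_raises(self):
        spec, base = _two_region_system()
        ens = make_ensemble(spec, [base])
        with pytest.raises(AnnotationError):
            hbond_footprint([ens], [], [4, 5])

    def test_absent_bond_scores_zero(self):
        spec, base = _two_region_system()
        ens = make_ensemble(spec, [base])
        fp = hbond_footprint([ens], [0, 1, 2, 3], [4, 5])
        assert fp.score("P", 9) == 0.0


def _mc_sasa_oracle(centers, radii, probe, n_points=200_000, seed=0):
    """Monte-Carlo surface-area oracle, independent of the spiral-point path."""
    rng = np.random.default_rng(seed)
    total = 0.0
    for i, (c, r) in enumerate(zip(centers, radii)):
        rr = r + probe
        pts = rng.normal(size=(n_points, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        surf = c + rr * pts
        exposed = np.ones(n_points, dtype=bool)
        for j, (c2, r2) in enumerate(zip(centers, radii)):
            if j != i:
                exposed &= np.sum((surf - c2) ** 2, axis=1) > (r2 + probe) ** 2
        total += 4 * np.pi * rr**2 * exposed.mean()
    return total


class TestSasa:
    def test_isolated_atom_closed_form(self):
        elements = np.array(["X"], dtype=object)
        per_res, total = sasa_frame(np.zeros((1, 3)), elements, [0],
                                    probe_radius_nm=0.14, radii={"X": 0.15})
        want = 4 * np.pi * 0.29**2
        assert total == pytest.approx(want, rel=1e-6)
        assert sum(per_res.values()) == pytest.approx(total, abs=1e-9)

    def test_distant_atoms_additive(self):
        elements = np.array(["O", "O"], dtype=object)
        coords = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        _, total = sasa_frame(coords, elements, [0, 1])
        single = 4 * np.pi * (VDW_RADII_NM["O"] + 0.14) ** 2
        assert total == pytest.approx(2 * single, rel=1e-6)

    def test_overlapping_pair_matches_grid_oracle(self):
        elements = np.array(["O", "N"], dtype=object)
        coords = np.array([[0.0, 0, 0], [0.2, 0, 0]])
        _, total = sasa_frame(coords, elements, [0, 1])
        want = _mc_sasa_oracle(coords, [VDW_RADII_NM["O"], VDW_RADII_NM["N"]], 0.14)
        assert total == pytest.approx(want, rel=0.01)

    def test_occluder_never_increases_area(self):
        rng = np.random.default_rng(11)
        elements3 = np.array(["O", "N", "C"], dtype=object)
        coords = rng.uniform(0, 0.5, size=(3, 3))
        per2, _ = sasa_frame(coords, elements3, [0, 1],
                             resids=np.array([1, 2, 3]),
                             chains=np.array(["A"] * 3, dtype=object))
        per3, _ = sasa_frame(coords, elements3, [0, 1, 2],
                             resids=np.array([1, 2, 3]),
                             chains=np.array(["A"] * 3, dtype=object))
        for key in per2:
            assert per3[key] <= per2[key] + 1e-12

    def test_scale_law(self):
        rng = np.random.default_rng(12)
        coords = rng.uniform(0, 0.4, size=(4, 3))
        elements = np.array(["O", "N", "C", "S"], dtype=object)
        k = 2.5
        _, a1 = sasa_frame(coords, elements, range(4))
        scaled_radii = {e: k * r for e, r in VDW_RADII_NM.items()}
        _, a2 = sasa_frame(k * coords, elements, range(4),
                           probe_radius_nm=k * 0.14, radii=scaled_radii)
        assert a2 == pytest.approx(k**2 * a1, rel=1e-9)

    def test_unknown_element_raises(self):
        elements = np.array(["Q"], dtype=object)
        with pytest.raises(AnnotationError):
            sasa_frame(np.zeros((1, 3)), elements, [0])

    def test_per_residue_sums_to_total(self):
        rng = np.random.default_rng(13)
        coords = rng.uniform(0, 0.6, size=(6, 3))
        elements = np.array(["O", "N", "C", "C", "O", "N"], dtype=object)
        per, total = sasa_frame(coords, elements, range(6),
                                chains=np.array(list("AAABBB"), dtype=object),
                                resids=np.array([1, 1, 2, 1, 1, 2]))
        assert sum(per.values()) == pytest.approx(total, abs=1e-9)

    def test_sphere_points_are_unit_and_spread(self):
        pts = sphere_points(960)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
        assert np.linalg.norm(pts.mean(axis=0)) < 0.01


BACKBONE_SPEC = [(n, n[0], r + 1, "A") for r in range(10) for n in ("N", "CA", "C", "O")]


class TestRmsf:
    def test_identical_frames_zero(self):
        rng = np.random.default_rng(20)
        base = rng.uniform(0, 2, size=(40, 3))
        ens = make_ensemble(BACKBONE_SPEC, [base] * 5)
        values = rmsf(ens, np.arange(40))
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in values.values())

    def test_gaussian_jitter_closed_form(self):
        # iid jitter sigma per coordinate -> per-atom RMSF = sigma * sqrt(3)
        rng = np.random.default_rng(21)
        sigma = 0.05
        base = rng.uniform(0, 2, size=(40, 3))
        frames = base + rng.normal(0, sigma, size=(2000, 40, 3))
        ens = make_ensemble(BACKBONE_SPEC, frames,
                            times=np.arange(1, 2001, dtype=float))
        values = np.array(list(rmsf(ens, np.arange(40)).values()))
        assert values.mean() == pytest.approx(sigma * np.sqrt(3), rel=0.03)

    def test_rigid_rotations_with_fitting_vanish(self):
        rng = np.random.default_rng(22)
        base = rng.uniform(0, 2, size=(40, 3))
        frames = []
        for _ in range(8):
            rot = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
            frames.append(base @ rot.T + rng.normal(0, 1, 3))
        ens = make_ensemble(BACKBONE_SPEC, frames)
        values = rmsf(ens, np.arange(40), fit_selection=np.arange(40))
        assert all(v <= 1e-6 for v in values.values())

    def test_rigid_transform_invariance_with_fitting(self):
        rng = np.random.default_rng(23)
        base = rng.uniform(0, 2, size=(40, 3))
        frames = base + rng.normal(0, 0.03, size=(30, 40, 3))
        ens = make_ensemble(BACKBONE_SPEC, frames)
        ref = rmsf(ens, np.arange(40), fit_selection=np.arange(40))
        rot = Rotation.random(random_state=99).as_matrix()
        moved = make_ensemble(BACKBONE_SPEC, frames @ rot.T + np.array([1.0, -2.0, 3.0]))
        got = rmsf(moved, np.arange(40), fit_selection=np.arange(40))
        for key in ref:
            assert got[key] == pytest.approx(ref[key], abs=1e-9)

    def test_single_frame_raises(self):
        ens = make_ensemble(BACKBONE_SPEC, np.zeros((1, 40, 3)))
        with pytest.raises(UndefinedFluctuationError):
            rmsf(ens, np.arange(40))

    def test_per_residue_mean_over_backbone(self):
        # atoms of one residue share the residue key
        ens = make_ensemble(BACKBONE_SPEC,
                            np.random.default_rng(24).normal(size=(10, 40, 3)))
        values = rmsf(ens, np.arange(40))
        assert set(values) == {("A", r + 1) for r in range(10)}
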