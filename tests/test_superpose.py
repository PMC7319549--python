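import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from oracles import brute_force_rmsd
from waterloan.homolog_search import align_pair
from waterloan.placement import PlacementConfig, place_waters
from waterloan.superpose import (
    DegenerateGeometryError,
    global_fit,
    kabsch_fit,
    local_refine_water,
)
from waterloan.water_db import build_template_entry

from conftest import rigid_move_model


def random_rigid(rng):
    return Rotation.random(random_state=rng).as_matrix(), rng.uniform(-30, 30, 3)


class TestKabschFit:
    def test_identity_on_identical_sets(self):
        pts = np.random.default_rng(0).uniform(-10, 10, (8, 3))
        fit = kabsch_fit(pts, pts)
        assert fit.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(fit.transform.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(fit.transform.translation, 0.0, atol=1e-12)

    def test_recovers_known_rigid_motion(self):
        pts = np.random.default_rng(1).uniform(-10, 10, (6, 3))
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        t = np.array([1.0, 2.0, 3.0])
        fit = kabsch_fit(pts, pts @ R.T + t)
        assert fit.rmsd <= 1e-9
        np.testing.assert_allclose(fit.transform.rotation, R, atol=1e-9)
        np.testing.assert_allclose(fit.transform.translation, t, atol=1e-9)

    def test_recovers_random_rigid_motions(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            pts = rng.uniform(-20, 20, (rng.integers(3, 12), 3))
            if np.linalg.svd(pts - pts.mean(0), compute_uv=False)[1] < 1e-6:
                continue
            R, t = random_rigid(rng)
            fit = kabsch_fit(pts, pts @ R.T + t)
            assert fit.rmsd <= 1e-9

    def test_matches_brute_force_on_jittered_sets(self):
        rng = np.random.default_rng(3)
        for n in (4, 5):
            pts = rng.uniform(-8, 8, (n, 3))
            R, t = random_rigid(rng)
            moved = pts @ R.T + t + rng.normal(0, 0.5, (n, 3))
            fit = kabsch_fit(pts, moved)
            brute = brute_force_rmsd(pts, moved, n_grid=3000, seed=9)
            assert fit.rmsd <= brute + 1e-4
            assert abs(fit.rmsd - brute) <= 1e-4

    def test_rotation_always_proper_even_near_reflection(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(-5, 5, (5, 3))
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        fit = kabsch_fit(pts, mirrored)
        assert np.linalg.det(fit.transform.rotation) == pytest.approx(1.0, abs=1e-9)
        RtR = fit.transform.rotation.T @ fit.transform.rotation
        np.testing.assert_allclose(RtR, np.eye(3), atol=1e-9)

    def test_optimality_vs_random_transforms(self):
        rng = np.random.default_rng(11)
        pts = rng.uniform(-10, 10, (7, 3))
        moved = pts + rng.normal(0, 1.0, (7, 3))
        fit = kabsch_fit(pts, moved)
        for _ in range(500):
            R, _ = random_rigid(rng)
            trial = pts @ R.T
            trial += moved.mean(0) - trial.mean(0)
            rmsd = np.sqrt(np.mean(np.sum((trial - moved) ** 2, axis=1)))
            assert fit.rmsd <= rmsd + 1e-12

    def test_degenerate_inputs_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(DegenerateGeometryError):
            kabsch_fit(line, line)
        with pytest.raises(ValueError):
            kabsch_fit(np.zeros((2, 3)), np.zeros((2, 3)))


@pytest.fixture(scope="module")
def identity_setup(small_family):
    model = small_family[0].model
    entry = build_template_entry(model, "REC", chain_id="A", resolution=2.0)
    bare = model.copy()
    for cid in list(bare.chains):
        bare.chains[cid] = [r for r in bare.chains[cid] if not r.is_water]
    aln = align_pair(entry.sequence, entry.sequence)
    return bare, entry, aln


class TestGlobalFit:
    def test_exact_copy_gives_zero_rmsd(self, identity_setup):
        query, entry, aln = identity_setup
        fit = global_fit(query, "A", entry, aln.correspondence)
        assert fit is not None
        assert fit.rmsd <= 1e-9
        assert fit.n_pairs == len(entry.backbone)

    def test_displaced_loop_rejected_as_outliers(self, identity_setup):
        query, entry, aln = identity_setup
        import copy

        distorted = copy.deepcopy(entry)
        moved = list(range(10, 15))  # one 5-residue stretch shifted 8 Å
        for ti in moved:
            for name in distorted.backbone[ti].atoms:
                distorted.backbone[ti].atoms[name] = (
                    distorted.backbone[ti].atoms[name] + np.array([8.0, 0, 0])
                )
        fit = global_fit(query, "A", distorted, aln.correspondence)
        assert fit is not None
        assert fit.rmsd < 0.5
        used_ti = {ti for _, ti in fit.pairs_used}
        assert not (used_ti & set(moved))

    def test_tiny_correspondence_skipped(self, identity_setup):
        query, entry, aln = identity_setup
        assert global_fit(query, "A", entry, aln.correspondence[:2]) is None


class TestLocalRefine:
    def test_identity_template_keeps_water(self, identity_setup):
        from waterloan.superpose import RigidTransform

        query, entry, aln = identity_setup
        for w in entry.waters:
            lp = local_refine_water(
                w, entry, query, "A", aln.correspondence,
            )
            assert lp.accepted
            assert lp.fit.rmsd <= 1e-9
            np.testing.assert_allclose(lp.position, w.coords, atol=1e-9)

    def test_local_distortion_rejects_only_affected_water(self, identity_setup):
        import copy

        query, entry, aln = identity_setup
        distorted = copy.deepcopy(entry)
        target = distorted.waters[0]
        rng = np.random.default_rng(2)
        # scramble backbone atoms near the first water to push local RMSD > 2 Å
        for ti, rc in enumerate(distorted.backbone):
            coords = np.array(list(rc.atoms.values()))
            if np.min(np.linalg.norm(coords - target.coords, axis=1)) <= 10.0:
                for name in rc.atoms:
                    rc.atoms[name] = rc.atoms[name] + rng.normal(0, 2.5, 3)
        lp = local_refine_water(target, distorted, query, "A", aln.correspondence)
        assert not lp.accepted
        assert lp.reason == "rmsd_exceeded"
        far = max(
            distorted.waters,
            key=lambda w: np.linalg.norm(w.coords - target.coords),
        )
        if np.linalg.norm(far.coords - target.coords) > 20.0:
            assert local_refine_water(
                far, distorted, query, "A", aln.correspondence
            ).accepted

    def test_too_few_local_pairs_rejected(self, identity_setup):
        query, entry, aln = identity_setup
        lp = local_refine_water(
            entry.waters[0], entry, query, "A", aln.correspondence[:2]
        )
        assert not lp.accepted
        assert lp.reason == "insufficient_local_pairs"

    def test_equivariance_under_query_motion(self, small_family, small_db):
        """Rigidly moving the query moves every placed water identically."""
        from waterloan.water_db import template_to_structure

        entry = small_db.entries[0]
        query = template_to_structure(entry)
        rng = np.random.default_rng(17)
        R, t = random_rigid(rng)
        moved_query = rigid_move_model(query, R, t)
        cfg = PlacementConfig()
        db_view = small_db.exclude_entry(entry.entry_id)
        _, rep1 = place_waters(query, db_view, cfg, chain_id="A")
        _, rep2 = place_waters(moved_query, db_view, cfg, chain_id="A")
        assert len(rep1.placed) == len(rep2.placed)
        p1 = np.array([w.coords for w in rep1.placed])
        p2 = np.array([w.coords for w in rep2.placed])
        np.testing.assert_allclose(p1 @ R.T + t, p2, atol=1e-6)
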