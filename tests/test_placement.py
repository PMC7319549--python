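import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from waterloan.placement import (
    PlacementConfig,
    check_clash,
    merge_external_predictions,
    place_waters,
)
from waterloan.structure_io import Atom, Residue
from waterloan.synth_fixtures import (
    FixtureSpec,
    family_reference_db,
    generate_family,
)
from waterloan.validation import water_recovery
from waterloan.water_db import ReferenceDB, template_to_structure

from conftest import rigid_move_model


class TestCheckClash:
    @pytest.mark.parametrize(
        "distance,expected",
        [(2.39, True), (2.40, False), (2.41, False)],
        ids=["just-inside", "exactly-at-cutoff", "just-outside"],
    )
    def test_strict_boundary(self, distance, expected):
        occupied = np.array([[distance, 0.0, 0.0]])
        assert check_clash(np.zeros(3), occupied, 2.4) is expected

    def test_empty_occupancy_never_clashes(self):
        assert not check_clash(np.zeros(3), np.empty((0, 3)), 2.4)


def _bare_query(entry):
    return template_to_structure(entry, include_waters=False)


class TestPlaceWaters:
    def test_identity_template_replaces_all_waters(self, small_db):
        entry = small_db.entries[0]
        query = _bare_query(entry)
        hydrated, report = place_waters(query, small_db, PlacementConfig(), chain_id="A")
        placed = np.array([w.coords for w in report.placed])
        orig = np.array([w.coords for w in entry.waters])
        rec = water_recovery(orig, placed, cutoff=2.0)
        assert rec.pct_recovery == 100.0
        # identity alignment: positions reproduced to numerical precision
        assert rec.mean_distance <= 1e-6
        assert len(hydrated.waters) == len(report.placed)

    def test_duplicate_template_contributes_nothing(self, small_db):
        import copy

        entry = small_db.entries[0]
        clone = copy.deepcopy(entry)
        clone.entry_id = "CLONE"
        for w in clone.waters:
            w.source_entry = "CLONE"
        db = ReferenceDB(entries=[entry, clone])
        query = _bare_query(entry)
        _, report = place_waters(query, db, PlacementConfig(), chain_id="A")
        by_template = dict(
            ((eid, ch), n) for eid, ch, n in report.templates_used
        )
        counts = sorted(by_template.values(), reverse=True)
        assert counts[0] == len(entry.waters)
        assert counts[1] == 0
        assert all(
            r.reason == "clash_water"
            for r in report.rejected
            if r.source_entry == "CLONE" or r.source_entry == entry.entry_id
        )

    def test_report_partitions_all_candidates(self, small_db):
        entry = small_db.entries[0]
        query = _bare_query(entry)
        db_view = small_db.exclude_entry(entry.entry_id)
        _, report = place_waters(query, db_view, PlacementConfig(), chain_id="A")
        n_candidates = sum(len(e.waters) for e in db_view.entries)
        n_accounted = len(report.placed) + sum(
            1 for r in report.rejected if r.reason != "below_threshold"
        )
        assert n_accounted == n_candidates

    def test_no_templates_above_threshold_returns_unchanged(self, small_db):
        entry = small_db.entries[0]
        query = _bare_query(entry)
        cfg = PlacementConfig(score_min=1e6)
        hydrated, report = place_waters(query, small_db, cfg, chain_id="A")
        assert report.placed == []
        assert hydrated.n_atoms() == query.n_atoms()
        assert all(r.reason == "below_threshold" for r in report.rejected)

    def test_clash_floor_holds_in_every_output(self, small_db):
        for entry in small_db.entries[:3]:
            query = _bare_query(entry)
            db_view = small_db.exclude_entry(entry.entry_id)
            _, report = place_waters(query, db_view, PlacementConfig(), chain_id="A")
            placed = np.array([w.coords for w in report.placed]).reshape(-1, 3)
            if len(placed) >= 2:
                d = np.linalg.norm(
                    placed[:, None, :] - placed[None, :, :], axis=2
                )
                np.fill_diagonal(d, np.inf)
                assert d.min() >= 2.4
            prot = query.heavy_coords(include_waters=False)
            for pos in placed:
                assert np.min(np.linalg.norm(prot - pos, axis=1)) >= 2.4

    def test_placement_is_deterministic(self, small_db, tmp_path):
        from waterloan.structure_io import write_pdb

        entry = small_db.entries[1]
        query = _bare_query(entry)
        db_view = small_db.exclude_entry(entry.entry_id)
        out = []
        for tag in ("a", "b"):
            hydrated, report = place_waters(query, db_view, PlacementConfig(), chain_id="A")
            p = tmp_path / f"{tag}.pdb"
            write_pdb(hydrated, p)
            t = tmp_path / f"{tag}.tsv"
            t.write_text(report.to_dataframe().to_csv(sep="\t", index=False))
            out.append((p.read_bytes(), t.read_bytes()))
        assert out[0] == out[1]

    def test_rehydrating_hydrated_output_adds_nothing(self, small_db):
        entry = small_db.entries[2]
        query = _bare_query(entry)
        db_view = small_db.exclude_entry(entry.entry_id)
        cfg = PlacementConfig()
        hydrated, rep1 = place_waters(query, db_view, cfg, chain_id="A")
        rehydrated, rep2 = place_waters(hydrated, db_view, cfg, chain_id="A")
        assert len(rep2.placed) == 0
        assert rehydrated.n_atoms() == hydrated.n_atoms()

    def test_provenance_round_trips_to_db_records(self, small_db):
        entry = small_db.entries[0]
        query = _bare_query(entry)
        db_view = small_db.exclude_entry(entry.entry_id)
        _, report = place_waters(query, db_view, PlacementConfig(), chain_id="A")
        by_entry = {e.entry_id: e for e in db_view.entries}
        for w in report.placed:
            assert w.source_entry in by_entry
            bfs = [x.bfactor for x in by_entry[w.source_entry].waters]
            assert any(abs(b - w.source_bfactor) < 1e-9 for b in bfs)

    def test_pre_existing_query_waters_are_respected(self, small_db):
        entry = small_db.entries[0]
        query = template_to_structure(entry, include_waters=True)
        db_view = ReferenceDB(entries=[e for e in small_db.entries])
        _, report = place_waters(query, db_view, PlacementConfig(), chain_id="A")
        existing = np.array(
            [r.oxygen.coords for r in query.waters]
        ).reshape(-1, 3)
        for w in report.placed:
            assert np.min(np.linalg.norm(existing - w.coords, axis=1)) >= 2.4


@pytest.fixture(scope="module")
def sodium_family():
    spec = FixtureSpec(seed=31, n_helices=7, helix_length=24, family_size=4,
                       n_cavity_waters=4, n_surface_waters=2, plant_sodium=True)
    fam = generate_family(spec)
    return fam, family_reference_db(fam)


class TestPlaceSodium:
    def test_open_pocket_gets_ion(self, sodium_family):
        fam, db = sodium_family
        entry = db.entries[0]
        query = _bare_query(entry)
        cfg = PlacementConfig(add_sodium=True)
        db_view = db.exclude_entry(entry.entry_id)
        _, report = place_waters(query, db_view, cfg, chain_id="A")
        assert report.sodium is not None
        pos = report.sodium.coords
        prot = query.heavy_coords(include_waters=False)
        assert np.min(np.linalg.norm(prot - pos, axis=1)) >= 1.8
        # waters placed later must clear the ion at the clash cutoff
        for w in report.placed:
            assert np.linalg.norm(w.coords - pos) >= 2.4

    def test_bulky_protein_atom_blocks_ion(self, sodium_family):
        fam, db = sodium_family
        entry = db.entries[0]
        db_view = db.exclude_entry(entry.entry_id)
        cfg = PlacementConfig(add_sodium=True)
        # find where the ion would land, then plant an atom 1.5 Å away
        query = _bare_query(entry)
        _, probe = place_waters(query, db_view, cfg, chain_id="A")
        assert probe.sodium is not None
        blocked = _bare_query(entry)
        res0 = blocked.protein_residues("A")[0]
        res0.atoms.append(
            Atom(name="CB", element="C",
                 coords=probe.sodium.coords + np.array([1.5, 0, 0]))
        )
        _, report = place_waters(blocked, db_view, cfg, chain_id="A")
        assert report.sodium is None
        assert report.sodium_reason == "protein_within_1.8"

    def test_nearby_water_blocks_ion(self, sodium_family):
        fam, db = sodium_family
        entry = db.entries[0]
        db_view = db.exclude_entry(entry.entry_id)
        cfg = PlacementConfig(add_sodium=True)
        query = _bare_query(entry)
        _, probe = place_waters(query, db_view, cfg, chain_id="A")
        blocked = _bare_query(entry)
        wres = Residue(chain_id="A", seq_number=4000, insertion_code="",
                       res_name="HOH")
        wres.atoms.append(
            Atom(name="O", element="O",
                 coords=probe.sodium.coords + np.array([0, 2.0, 0]))
        )
        blocked.add_residue(wres)
        _, report = place_waters(blocked, db_view, cfg, chain_id="A")
        assert report.sodium is None
        assert report.sodium_reason == "water_within_2.1"

    def test_no_template_with_ion_logs_reason(self, small_db):
        entry = small_db.entries[0]
        query = _bare_query(entry)
        cfg = PlacementConfig(add_sodium=True)
        _, report = place_waters(query, small_db, cfg, chain_id="A")
        assert report.sodium is None
        assert report.sodium_reason == "no_template_with_na"


class TestMergeExternal:
    def test_overlapping_prediction_dropped(self, small_db):
        entry = small_db.entries[0]
        query = _bare_query(entry)
        hydrated, report = place_waters(query, small_db, PlacementConfig(), chain_id="A")
        w0 = report.placed[0].coords
        far = w0 + np.array([50.0, 0, 0])
        far2 = w0 + np.array([0, 50.0, 0])
        preds = [w0 + np.array([0.5, 0, 0]), far, far2]
        merged, n_added, n_rejected = merge_external_predictions(hydrated, preds)
        assert (n_added, n_rejected) == (2, 1)
        assert len(merged.waters) == len(hydrated.waters) + 2

    def test_empty_prediction_list_is_noop(self, small_db):
        entry = small_db.entries[0]
        query = _bare_query(entry)
        merged, n_added, n_rejected = merge_external_predictions(
            query, np.empty((0, 3))
        )
        assert (n_added, n_rejected) == (0, 0)
        assert merged.n_atoms() == query.n_atoms()

    def test_prediction_duplicating_accepted_prediction_rejected(self, small_db):
        entry = small_db.entries[0]
        query = _bare_query(entry)
        pos = query.heavy_coords().mean(axis=0) + np.array([0, 0, 200.0])
        merged, n_added, n_rejected = merge_external_predictions(
            query, [pos, pos + np.array([1.0, 0, 0])]
        )
        assert (n_added, n_rejected) == (1, 1)
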