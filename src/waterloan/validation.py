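"""Recovery benchmarking: can the method re-create waters it has never
seen?

`water_recovery` matches placed waters to held-out original waters
one-to-one, greedily over all pairs in ascending distance, accepting a
pair only when its distance is strictly below the cutoff (2 Å by
default). `leave_one_out` runs the full protocol: each test entry is
stripped of its waters, every chain of that entry is removed from the
reference database, the structure is re-hydrated from the remaining
homologs, and recovery is scored against the held-out internal waters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError
from .placement import PlacementConfig, place_waters
from .water_db import ReferenceDB, template_to_structure

DEFAULT_RECOVERY_CUTOFF = 2.0  # Å, strict <

# benchmark test-set admission rule
TEST_SET_MAX_RESOLUTION = 2.8  # Å, strict <
TEST_SET_MIN_WATERS = 5  # strict >


@dataclass
class RecoveryResult:
    n_original: int
    n_recovered: int
    pct_recovery: float
    mean_distance: float
    matches: list[tuple[int, int, float]] = field(default_factory=list)
    no_matches: bool = False


def water_recovery(
    original: np.ndarray,
    placed: np.ndarray,
    cutoff: float = DEFAULT_RECOVERY_CUTOFF,
) -> RecoveryResult:
    """Greedy one-to-one matching of placed onto original waters.

    All (original, placed) pairs are visited in ascending distance; a
    pair is accepted iff its distance is strictly below ``cutoff`` and
    neither member is already matched. ``mean_distance`` is taken over
    matched pairs (0 with ``no_matches`` set when nothing matched).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    orig = np.asarray(original, dtype=float).reshape(-1, 3)
    plac = np.asarray(placed, dtype=float).reshape(-1, 3)
    if len(orig) == 0:
        raise DataError("no original waters to recover")
    matches: list[tuple[int, int, float]] = []
    if len(plac):
        d = np.linalg.norm(orig[:, None, :] - plac[None, :, :], axis=2)
        order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
        used_o: set[int] = set()
        used_p: set[int] = set()
        for oi, pi in order:
            dist = d[oi, pi]
            if dist >= cutoff:
                break
            if oi in used_o or pi in used_p:
                continue
            used_o.add(int(oi))
            used_p.add(int(pi))
            matches.append((int(oi), int(pi), float(dist)))
    n_rec = len(matches)
    return RecoveryResult(
        n_original=len(orig),
        n_recovered=n_rec,
        pct_recovery=100.0 * n_rec / len(orig),
        mean_distance=float(np.mean([m[2] for m in matches])) if matches else 0.0,
        matches=matches,
        no_matches=not matches,
    )


def select_test_entries(
    db: ReferenceDB,
    max_resolution: float = TEST_SET_MAX_RESOLUTION,
    min_waters: int = TEST_SET_MIN_WATERS,
) -> list[str]:
    """Entry ids eligible for the benchmark: resolution strictly below
    ``max_resolution`` and strictly more than ``min_waters`` internal
    waters."""
    return sorted(
        {
            e.entry_id
            for e in db.entries
            if e.resolution < max_resolution and len(e.waters) > min_waters
        }
    )


def leave_one_out(
    db: ReferenceDB,
    test_entries: list[str],
    cfg: PlacementConfig | None = None,
) -> pd.DataFrame:
    """Leave-one-out recovery over ``test_entries``.

    For each test id: every chain of that entry is excluded from the DB
    (avoiding self-template leakage), the entry's stored backbone — with
    its waters stripped — becomes the query, the query is re-hydrated,
    and recovery is computed against the held-out internal waters in the
    entry's own frame. One row per (entry, chain).
    """
    cfg = cfg or PlacementConfig()
    known = {e.entry_id for e in db.entries}
    missing = [t for t in test_entries if t not in known]
    if missing:
        raise DataError(f"test entries not in DB: {missing}; known ids: {sorted(known)}")
    rows = []
    for test_id in test_entries:
        held_out = [e for e in db.entries if e.entry_id == test_id]
        db_view = db.exclude_entry(test_id)
        for entry in held_out:
            query = template_to_structure(entry, include_waters=False)
            _, report = place_waters(query, db_view, cfg, chain_id=entry.chain_id)
            placed = np.array([w.coords for w in report.placed]).reshape(-1, 3)
            original = np.array([w.coords for w in entry.waters]).reshape(-1, 3)
            rec = water_recovery(original, placed, cfg.recovery_cutoff)
            rows.append(
                {
                    "entry": entry.entry_id,
                    "chain": entry.chain_id,
                    "n_original": rec.n_original,
                    "n_recovered": rec.n_recovered,
                    "pct_recovery": rec.pct_recovery,
                    "mean_distance": rec.mean_distance,
                    "n_placed": len(report.placed),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "entry", "chain", "n_original", "n_recovered",
            "pct_recovery", "mean_distance", "n_placed",
        ],
    )
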