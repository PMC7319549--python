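"""The hydration engine: transfer internal waters from ranked homologous
templates onto a query structure.

Template order follows the ranking (state priority, bit score
descending, resolution ascending). Within each template, candidate
waters are assessed one by one in increasing source B-factor. A
candidate must first pass the local-superposition gate (≥3 residue
pairs, RMSD ≤ 2.0 Å) and is then accepted only if it does not clash —
come strictly within 2.4 Å — with any query heavy atom (protein,
ligands, pre-existing waters) or any already-placed water or ion.

The optional sodium ion (conserved site near residue 2.50 of inactive
receptors) is taken from the template with the highest sequence
identity (tie → best resolution) and placed before the waters, provided
no water lies within 2.1 Å and no protein atom within 1.8 Å of the
mapped position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .homolog_search import RankedTemplate, rank_templates
from .structure_io import Atom, Residue, StructureModel, extract_sequence
from .superpose import FitResult, global_fit, local_refine_water
from .water_db import ReferenceDB, WaterRecord

logger = logging.getLogger(__name__)

#: rejection reasons recorded in the placement report
REASONS = (
    "clash_protein",
    "clash_water",
    "rmsd_exceeded",
    "insufficient_local_pairs",
    "below_threshold",
    "no_global_fit",
)


@dataclass
class PlacementConfig:
    """All thresholds of the hydration pipeline (Å unless noted)."""

    clash_cutoff: float = 2.4
    na_water: float = 2.1  # sodium exclusion radius vs waters
    na_protein: float = 1.8  # sodium exclusion radius vs protein atoms
    score_min: float = 0.0  # bit-score threshold for templates
    query_state: str = "unknown"
    add_sodium: bool = False
    state_priority: bool = True
    local_radius: float = 10.0
    local_rmsd_max: float = 2.0
    external_merge_cutoff: float = 2.4
    recovery_cutoff: float = 2.0  # used by validation

    def __post_init__(self) -> None:
        for name in (
            "clash_cutoff",
            "na_water",
            "na_protein",
            "local_radius",
            "local_rmsd_max",
            "external_merge_cutoff",
            "recovery_cutoff",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class PlacedWater:
    coords: np.ndarray
    source_entry: str
    source_chain: str
    source_bfactor: float
    local_rmsd: float
    order_index: int


@dataclass
class RejectedWater:
    source_entry: str
    source_chain: str
    source_bfactor: float
    reason: str
    coords: np.ndarray | None = None  # mapped position when one exists
    local_rmsd: float | None = None


@dataclass
class PlacedIon:
    coords: np.ndarray
    element: str
    source_entry: str


@dataclass
class PlacementReport:
    placed: list[PlacedWater] = field(default_factory=list)
    rejected: list[RejectedWater] = field(default_factory=list)
    sodium: PlacedIon | None = None
    sodium_reason: str | None = None
    templates_used: list[tuple[str, str, int]] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for w in self.placed:
            rows.append(
                {
                    "index": w.order_index,
                    "x": w.coords[0],
                    "y": w.coords[1],
                    "z": w.coords[2],
                    "source_entry": w.source_entry,
                    "source_chain": w.source_chain,
                    "source_bfactor": w.source_bfactor,
                    "local_rmsd": w.local_rmsd,
                    "status": "placed",
                    "reason": "",
                }
            )
        for r in self.rejected:
            rows.append(
                {
                    "index": -1,
                    "x": r.coords[0] if r.coords is not None else np.nan,
                    "y": r.coords[1] if r.coords is not None else np.nan,
                    "z": r.coords[2] if r.coords is not None else np.nan,
                    "source_entry": r.source_entry,
                    "source_chain": r.source_chain,
                    "source_bfactor": r.source_bfactor,
                    "local_rmsd": r.local_rmsd if r.local_rmsd is not None else np.nan,
                    "status": "rejected",
                    "reason": r.reason,
                }
            )
        cols = [
            "index", "x", "y", "z", "source_entry", "source_chain",
            "source_bfactor", "local_rmsd", "status", "reason",
        ]
        return pd.DataFrame(rows, columns=cols)


def check_clash(
    position: np.ndarray, occupied: cKDTree | np.ndarray, cutoff: float
) -> bool:
    """True iff any occupied point lies strictly within ``cutoff`` Å."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    pos = np.asarray(position, dtype=float)
    if isinstance(occupied, cKDTree):
        d, _ = occupied.query(pos, k=1)
        return bool(d < cutoff)
    occ = np.asarray(occupied, dtype=float).reshape(-1, 3)
    if occ.size == 0:
        return False
    return bool(np.min(np.linalg.norm(occ - pos, axis=1)) < cutoff)


def _min_dist(pos: np.ndarray, pts: list[np.ndarray]) -> float:
    if not pts:
        return np.inf
    arr = np.asarray(pts, dtype=float).reshape(-1, 3)
    return float(np.min(np.linalg.norm(arr - pos, axis=1)))


def _auto_chain(query: StructureModel) -> str:
    counts = {
        cid: sum(1 for r in residues if r.is_amino)
        for cid, residues in query.chains.items()
    }
    counts = {c: n for c, n in counts.items() if n > 0}
    if not counts:
        raise ValueError("query has no protein chain")
    return max(sorted(counts), key=lambda c: counts[c])


def _water_chain_id(query: StructureModel) -> str:
    for cid in "WVUZYXw":
        if cid not in query.chains:
            return cid
    return "9"


def place_sodium(
    query: StructureModel,
    ranked: list[RankedTemplate],
    fits: dict[tuple[str, str], FitResult | None],
    protein_tree: cKDTree,
    existing_waters: list[np.ndarray],
    cfg: PlacementConfig,
) -> tuple[PlacedIon | None, str | None]:
    """Place the conserved sodium from the best-identity template.

    Candidate templates are those above threshold that carry an ion
    flagged near position 2.50 and have a usable global fit; the one
    with highest %identity wins (tie → best resolution, then entry id).
    The ion is accepted iff no water lies within ``cfg.na_water`` and no
    protein heavy atom within ``cfg.na_protein`` of the mapped position.
    """
    candidates = [
        rt
        for rt in ranked
        if any(i.near_250 for i in rt.template.ions)
        and fits.get(rt.template.key) is not None
    ]
    if not candidates:
        return None, "no_template_with_na"
    candidates.sort(
        key=lambda rt: (
            -rt.alignment.pct_identity,
            rt.template.resolution,
            rt.template.entry_id,
            rt.template.chain_id,
        )
    )
    best = candidates[0]
    fit = fits[best.template.key]
    ion = next(i for i in best.template.ions if i.near_250)
    pos = fit.transform.apply(ion.coords)
    if _min_dist(pos, existing_waters) < cfg.na_water:
        return None, "water_within_2.1"
    d_prot, _ = protein_tree.query(pos, k=1)
    if d_prot < cfg.na_protein:
        return None, "protein_within_1.8"
    return PlacedIon(coords=pos, element="NA", source_entry=best.template.entry_id), None


def place_waters(
    query: StructureModel,
    db: ReferenceDB,
    cfg: PlacementConfig | None = None,
    chain_id: str | None = None,
    ranked: list[RankedTemplate] | None = None,
) -> tuple[StructureModel, PlacementReport]:
    """Hydrate ``query`` with internal waters borrowed from the DB.

    Returns a copy of the query with accepted waters appended as HOH
    residues on a fresh chain (sequential numbering, source B-factor
    carried over; sodium as an NA residue), plus a report that accounts
    for every candidate water of every template above the score
    threshold. Deterministic for identical inputs.
    """
    cfg = cfg or PlacementConfig()
    chain_id = chain_id or _auto_chain(query)
    query_seq = extract_sequence(query, chain_id)
    report = PlacementReport(config=cfg.as_dict())

    if ranked is None:
        ranked = rank_templates(
            db,
            query_seq,
            query_state=cfg.query_state,
            score_min=cfg.score_min,
            state_priority=cfg.state_priority,
        )
        # account for templates excluded by the threshold
        ranked_keys = {rt.template.key for rt in ranked}
        for entry in db.entries:
            if entry.key not in ranked_keys:
                for w in entry.waters:
                    report.rejected.append(
                        RejectedWater(
                            source_entry=w.source_entry,
                            source_chain=w.source_chain,
                            source_bfactor=w.bfactor,
                            reason="below_threshold",
                        )
                    )
    if not ranked:
        logger.info("no templates above threshold; query returned unchanged")
        return query.copy(), report

    protein_pts = [
        a.coords for r, a in query.iter_atoms() if not r.is_water
    ]
    protein_tree = cKDTree(np.asarray(protein_pts, dtype=float).reshape(-1, 3))
    existing_waters = [
        r.oxygen.coords for r in query.waters if r.oxygen is not None
    ]

    fits: dict[tuple[str, str], FitResult | None] = {}
    for rt in ranked:
        fits[rt.template.key] = global_fit(
            query, chain_id, rt.template, rt.alignment.correspondence
        )

    if cfg.add_sodium:
        report.sodium, report.sodium_reason = place_sodium(
            query, ranked, fits, protein_tree, existing_waters, cfg
        )

    placed_pts: list[np.ndarray] = []
    if report.sodium is not None:
        placed_pts.append(report.sodium.coords)

    order_index = 0
    for rt in ranked:
        entry = rt.template
        fit = fits[entry.key]
        n_placed_here = 0
        if fit is None:
            logger.info(
                "template %s:%s skipped: insufficient correspondence for global fit",
                entry.entry_id, entry.chain_id,
            )
            for w in entry.waters:
                report.rejected.append(
                    RejectedWater(
                        source_entry=w.source_entry,
                        source_chain=w.source_chain,
                        source_bfactor=w.bfactor,
                        reason="no_global_fit",
                    )
                )
            report.templates_used.append((entry.entry_id, entry.chain_id, 0))
            continue
        # ascending source B-factor; ties keep source record order
        order = sorted(range(len(entry.waters)), key=lambda i: (entry.waters[i].bfactor, i))
        for wi in order:
            w: WaterRecord = entry.waters[wi]
            lp = local_refine_water(
                w, entry, query, chain_id, rt.alignment.correspondence,
                radius=cfg.local_radius, rmsd_max=cfg.local_rmsd_max,
            )
            if not lp.accepted:
                report.rejected.append(
                    RejectedWater(
                        source_entry=w.source_entry,
                        source_chain=w.source_chain,
                        source_bfactor=w.bfactor,
                        reason=lp.reason,
                        local_rmsd=lp.fit.rmsd if lp.fit else None,
                    )
                )
                continue
            pos = lp.position
            if check_clash(pos, protein_tree, cfg.clash_cutoff):
                reason = "clash_protein"
            elif (
                _min_dist(pos, existing_waters) < cfg.clash_cutoff
                or _min_dist(pos, placed_pts) < cfg.clash_cutoff
            ):
                reason = "clash_water"
            else:
                reason = None
            if reason:
                report.rejected.append(
                    RejectedWater(
                        source_entry=w.source_entry,
                        source_chain=w.source_chain,
                        source_bfactor=w.bfactor,
                        reason=reason,
                        coords=pos,
                        local_rmsd=lp.fit.rmsd,
                    )
                )
                continue
            order_index += 1
            report.placed.append(
                PlacedWater(
                    coords=pos,
                    source_entry=w.source_entry,
                    source_chain=w.source_chain,
                    source_bfactor=w.bfactor,
                    local_rmsd=lp.fit.rmsd,
                    order_index=order_index,
                )
            )
            placed_pts.append(pos)
            n_placed_here += 1
        report.templates_used.append((entry.entry_id, entry.chain_id, n_placed_here))

    hydrated = attach_waters(query, report)
    return hydrated, report


def attach_waters(query: StructureModel, report: PlacementReport) -> StructureModel:
    """Copy of the query with placed waters (and ion) as new residues."""
    out = query.copy()
    wchain = _water_chain_id(query)
    for w in report.placed:
        res = Residue(
            chain_id=wchain,
            seq_number=w.order_index,
            insertion_code="",
            res_name="HOH",
        )
        res.atoms.append(
            Atom(name="O", element="O", coords=np.array(w.coords), bfactor=w.source_bfactor)
        )
        out.add_residue(res)
    if report.sodium is not None:
        res = Residue(
            chain_id=wchain,
            seq_number=len(report.placed) + 1,
            insertion_code="",
            res_name="NA",
        )
        res.atoms.append(
            Atom(name="NA", element="NA", coords=np.array(report.sodium.coords))
        )
        out.add_residue(res)
    return out


def merge_external_predictions(
    model: StructureModel,
    predicted: list[np.ndarray] | np.ndarray,
    cutoff: float = 2.4,
) -> tuple[StructureModel, int, int]:
    """Add externally predicted waters that do not overlap existing atoms.

    A prediction is accepted iff it lies at least ``cutoff`` Å from every
    atom of the model and from every previously accepted prediction
    (same strict-inequality rule as the clash filter). Accepted waters
    are tagged with source ``external``. Returns (model, n_added,
    n_rejected).
    """
    preds = [np.asarray(p, dtype=float) for p in np.asarray(predicted, dtype=float).reshape(-1, 3)]
    out = model.copy()
    if not preds:
        return out, 0, 0
    all_pts = out.heavy_coords(include_waters=True)
    tree = cKDTree(all_pts) if all_pts.size else None
    wchain = None
    for cid, residues in out.chains.items():
        if residues and all(r.is_water for r in residues):
            wchain = cid
    if wchain is None:
        wchain = _water_chain_id(out)
    start = max(
        (r.seq_number for r in out.chains.get(wchain, [])), default=0
    )
    accepted: list[np.ndarray] = []
    n_added = n_rejected = 0
    for pos in preds:
        clash = (tree is not None and check_clash(pos, tree, cutoff)) or check_clash(
            pos, np.asarray(accepted).reshape(-1, 3), cutoff
        )
        if clash:
            n_rejected += 1
            continue
        n_added += 1
        accepted.append(pos)
        res = Residue(
            chain_id=wchain,
            seq_number=start + n_added,
            insertion_code="",
            res_name="HOH",
        )
        res.atoms.append(Atom(name="O", element="O", coords=pos))
        out.add_residue(res)
    out.metadata.setdefault("external_waters", 0)
    out.metadata["external_waters"] += n_added
    return out, n_added, n_rejected
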