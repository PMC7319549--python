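"""Rigid-body superposition: global template→query fit and per-water
local refinement.

The global fit is a least-squares (Kabsch/SVD) superposition of
corresponded Cα atoms with iterative outlier rejection (pairs with a
residual above 2 σ are dropped and the fit repeated, up to five
cycles). Each candidate water is then refined by re-fitting on the
backbone atoms (N, Cα, C, O) of corresponded residues that have any
stored atom within 10 Å of the water oxygen in the template frame; only
waters whose local fit reaches at most 2.0 Å RMSD over at least three
residue pairs are kept, and the kept water is mapped by the *local*
transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import StructureModel
from .water_db import BACKBONE_ATOMS, TemplateEntry, WaterRecord

DEFAULT_LOCAL_RADIUS = 10.0  # Å
DEFAULT_LOCAL_RMSD_MAX = 2.0  # Å
DEFAULT_OUTLIER_SIGMA = 2.0
DEFAULT_MAX_CYCLES = 5
MIN_PAIRS = 3


@dataclass
class RigidTransform:
    """Proper rigid motion x ↦ R·x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class FitResult:
    transform: RigidTransform
    rmsd: float
    n_pairs: int
    pairs_used: list = field(default_factory=list)


@dataclass
class LocalPlacement:
    """Outcome of local refinement for one candidate water."""

    accepted: bool
    position: np.ndarray | None = None
    fit: FitResult | None = None
    reason: str | None = None  # rmsd_exceeded | insufficient_local_pairs


class DegenerateGeometryError(ValueError):
    pass


def kabsch_fit(moving: np.ndarray, fixed: np.ndarray) -> FitResult:
    """Least-squares optimal proper rotation+translation of ``moving``
    onto ``fixed`` (Kabsch via SVD, with reflection correction)."""
    P = np.asarray(moving, dtype=float).reshape(-1, 3)
    Q = np.asarray(fixed, dtype=float).reshape(-1, 3)
    if P.shape != Q.shape:
        raise ValueError("point sets must have equal shapes")
    n = len(P)
    if n < MIN_PAIRS:
        raise ValueError(f"need at least {MIN_PAIRS} point pairs, got {n}")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - cp, Q - cq
    # collinear point sets leave the rotation about the line undetermined
    sv = np.linalg.svd(Pc, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise DegenerateGeometryError("moving points are (near-)collinear")
    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    tf = RigidTransform(R, t)
    resid = tf.apply(P) - Q
    rmsd = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return FitResult(transform=tf, rmsd=rmsd, n_pairs=n)


def _ca_pairs(
    query: StructureModel,
    chain_id: str,
    template: TemplateEntry,
    correspondence: list[tuple[int, int]],
) -> tuple[np.ndarray, np.ndarray, list]:
    qres = query.protein_residues(chain_id)
    mov, fix, locs = [], [], []
    for qi, ti in correspondence:
        if not (0 <= qi < len(qres) and 0 <= ti < len(template.backbone)):
            continue
        qa = qres[qi].atom("CA")
        tb = template.backbone[ti].atoms.get("CA")
        if qa is None or tb is None:
            continue
        mov.append(tb)
        fix.append(qa.coords)
        locs.append((qres[qi].locator, ti))
    return (
        np.asarray(mov, dtype=float).reshape(-1, 3),
        np.asarray(fix, dtype=float).reshape(-1, 3),
        locs,
    )


def global_fit(
    query: StructureModel,
    chain_id: str,
    template: TemplateEntry,
    correspondence: list[tuple[int, int]],
    outlier_sigma: float = DEFAULT_OUTLIER_SIGMA,
    max_cycles: int = DEFAULT_MAX_CYCLES,
) -> FitResult | None:
    """Kabsch fit on corresponded Cα atoms with outlier rejection.

    Returns ``None`` when fewer than three usable pairs exist (caller
    skips the template). Pairs whose residual exceeds ``outlier_sigma``
    times the RMS residual are dropped and the fit repeated, up to
    ``max_cycles`` times or until the pair set is stable.
    """
    mov, fix, locs = _ca_pairs(query, chain_id, template, correspondence)
    if len(mov) < MIN_PAIRS:
        return None
    keep = np.ones(len(mov), dtype=bool)
    fit = None
    for _ in range(max(1, max_cycles)):
        try:
            fit = kabsch_fit(mov[keep], fix[keep])
        except DegenerateGeometryError:
            return None
        resid = np.linalg.norm(fit.transform.apply(mov) - fix, axis=1)
        sigma = np.sqrt(np.mean(resid[keep] ** 2))
        if sigma <= 1e-12:
            break
        new_keep = keep & (resid <= outlier_sigma * sigma)
        if new_keep.sum() < MIN_PAIRS or np.array_equal(new_keep, keep):
            break
        keep = new_keep
    assert fit is not None
    fit.pairs_used = [loc for loc, k in zip(locs, keep) if k]
    fit.n_pairs = int(keep.sum())
    return fit


def local_refine_water(
    water: WaterRecord,
    template: TemplateEntry,
    query: StructureModel,
    chain_id: str,
    correspondence: list[tuple[int, int]],
    radius: float = DEFAULT_LOCAL_RADIUS,
    rmsd_max: float = DEFAULT_LOCAL_RMSD_MAX,
) -> LocalPlacement:
    """Refine one candidate water by a local backbone fit around it.

    Template residues with any stored atom within ``radius`` of the
    water oxygen (template frame) and present in the correspondence are
    fitted on their backbone atoms; the water is mapped by the local
    transform iff the fit uses ≥ 3 residue pairs and its RMSD is at most
    ``rmsd_max``.
    """
    qres = query.protein_residues(chain_id)
    mov, fix = [], []
    n_res_pairs = 0
    for qi, ti in correspondence:
        if not (0 <= qi < len(qres) and 0 <= ti < len(template.backbone)):
            continue
        trc = template.backbone[ti]
        coords = np.array(list(trc.atoms.values()), dtype=float)
        if coords.size == 0:
            continue
        if np.min(np.linalg.norm(coords - water.coords, axis=1)) > radius:
            continue
        q = qres[qi]
        pair_atoms = 0
        for name in BACKBONE_ATOMS:
            ta = trc.atoms.get(name)
            qa = q.atom(name)
            if ta is not None and qa is not None:
                mov.append(ta)
                fix.append(qa.coords)
                pair_atoms += 1
        if pair_atoms:
            n_res_pairs += 1
    if n_res_pairs < MIN_PAIRS:
        return LocalPlacement(accepted=False, reason="insufficient_local_pairs")
    try:
        fit = kabsch_fit(np.asarray(mov), np.asarray(fix))
    except DegenerateGeometryError:
        return LocalPlacement(accepted=False, reason="insufficient_local_pairs")
    fit.n_pairs = n_res_pairs
    if fit.rmsd > rmsd_max:
        return LocalPlacement(accepted=False, fit=fit, reason="rmsd_exceeded")
    return LocalPlacement(
        accepted=True, position=fit.transform.apply(water.coords), fit=fit
    )
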