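"""Reference database of curated internal waters from template structures.

A template contributes only waters that are (i) well ordered — isotropic
B-factor at or below 45 Å² — and (ii) internal, i.e. buried in the
protein matrix. Burial is measured by circular variance (CV): the length
of the mean unit vector from the water oxygen to surrounding protein
heavy atoms within 10 Å. CV near 1 means neighbours surround the water
(buried); CV near 0 means they sit to one side (exposed). Waters with
CV < 0.6 are treated as external and discarded.

The database is serialised as versioned JSON-lines — one header line
followed by one template entry per line — so it is diffable and
portable. Each entry stores the receptor sequence, functional state,
resolution, backbone coordinates (for superposition), the curated
water records and any sodium ions near the conserved 2.50 position.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import DataError, SchemaVersionError
from .structure_io import Residue, StructureModel, extract_sequence

SCHEMA_VERSION = 1

DEFAULT_BFACTOR_MAX = 45.0  # Å², strict >
DEFAULT_CV_RADIUS = 10.0  # Å
DEFAULT_CV_THRESHOLD = 0.6
ION_NEAR_250_DIST = 6.0  # Å, generous capture; placement re-checks geometry

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class WaterRecord:
    """One curated internal water, in the template's coordinate frame."""

    coords: np.ndarray
    bfactor: float
    circ_var: float
    source_entry: str
    source_chain: str

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)


@dataclass
class IonRecord:
    element: str
    coords: np.ndarray
    source_entry: str
    near_250: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)


@dataclass
class ResidueCoords:
    """Backbone coordinates of one template residue."""

    chain_id: str
    seq_number: int
    insertion_code: str
    res_name: str
    atoms: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.atoms = {k: np.asarray(v, dtype=float) for k, v in self.atoms.items()}


@dataclass
class TemplateEntry:
    entry_id: str
    chain_id: str
    receptor_name: str
    sequence: str
    state: str  # active | inactive | unknown
    resolution: float
    waters: list[WaterRecord] = field(default_factory=list)
    ions: list[IonRecord] = field(default_factory=list)
    res_250: str | None = None  # "chain:number"
    backbone: list[ResidueCoords] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.entry_id}: empty sequence")
        if self.resolution <= 0:
            raise ValueError(f"{self.entry_id}: resolution must be > 0")

    @property
    def key(self) -> tuple[str, str]:
        return (self.entry_id, self.chain_id)


@dataclass
class ReferenceDB:
    entries: list[TemplateEntry] = field(default_factory=list)
    schema_version: int = SCHEMA_VERSION
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [e.key for e in self.entries]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (entry_id, chain_id) in reference DB")

    def exclude_entry(self, entry_id: str) -> "ReferenceDB":
        """View of the DB without every chain of one entry id."""
        return ReferenceDB(
            entries=[e for e in self.entries if e.entry_id != entry_id],
            schema_version=self.schema_version,
            provenance=dict(self.provenance),
        )


def circular_variance(
    water_oxygen: np.ndarray,
    neighbor_atoms: np.ndarray,
    radius: float = DEFAULT_CV_RADIUS,
) -> float:
    """CV = 1 − ‖Σ û‖ / N over unit vectors to neighbours within ``radius``.

    Coincident points are skipped; with no neighbours the water is by
    definition maximally exposed, so CV = 0 is returned with a warning.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    o = np.asarray(water_oxygen, dtype=float)
    nb = np.asarray(neighbor_atoms, dtype=float).reshape(-1, 3)
    if nb.size == 0:
        warnings.warn("circular_variance: no neighbor atoms; returning 0 (exposed)")
        return 0.0
    vec = nb - o
    dist = np.linalg.norm(vec, axis=1)
    mask = (dist > 1e-9) & (dist <= radius)
    if not np.any(mask):
        warnings.warn("circular_variance: no neighbors within radius; returning 0")
        return 0.0
    units = vec[mask] / dist[mask, None]
    return float(1.0 - np.linalg.norm(units.sum(axis=0)) / len(units))


def classify_water(
    water: Residue | np.ndarray,
    protein_atoms: np.ndarray,
    radius: float = DEFAULT_CV_RADIUS,
    cv_threshold: float = DEFAULT_CV_THRESHOLD,
) -> str:
    """Classify a water as ``"internal"`` or ``"external"`` by CV."""
    if isinstance(water, Residue):
        ox = water.oxygen
        if ox is None:
            raise DataError("water residue has no oxygen atom")
        pos = ox.coords
    else:
        pos = np.asarray(water, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cv = circular_variance(pos, protein_atoms, radius)
    return "internal" if cv >= cv_threshold else "external"


def _parse_res_250(res_250: str | tuple[str, int]) -> tuple[str, int]:
    if isinstance(res_250, tuple):
        return res_250
    chain, _, num = res_250.partition(":")
    try:
        return chain, int(num)
    except ValueError as exc:
        raise DataError(f"bad res_250 locator {res_250!r}; expected 'chain:number'") from exc


def build_template_entry(
    model: StructureModel,
    receptor_name: str,
    state: str = "unknown",
    res_250: str | tuple[str, int] | None = None,
    chain_id: str | None = None,
    resolution: float | None = None,
    bfactor_max: float = DEFAULT_BFACTOR_MAX,
    cv_threshold: float = DEFAULT_CV_THRESHOLD,
    cv_radius: float = DEFAULT_CV_RADIUS,
) -> TemplateEntry:
    """Curate one stripped template structure into a DB entry.

    Waters with B-factor strictly above ``bfactor_max`` are discarded
    first; survivors are classified by circular variance against the
    protein heavy atoms and only internal ones (CV ≥ threshold) are
    stored. Sodium ions are recorded, flagged when near residue 2.50.
    """
    if chain_id is None:
        candidates = sorted(
            {r.chain_id for r in model.iter_residues() if r.is_amino}
        )
        if not candidates:
            raise DataError(f"{model.entry_id}: no protein residues")
        if len(candidates) > 1:
            raise DataError(
                f"{model.entry_id}: multiple protein chains {candidates}; "
                "pass chain_id explicitly"
            )
        chain_id = candidates[0]
    protein = model.protein_residues(chain_id)
    if not protein:
        raise DataError(f"{model.entry_id}: chain {chain_id} has no protein residues")
    protein_xyz = np.array(
        [a.coords for r in protein for a in r.atoms], dtype=float
    ).reshape(-1, 3)

    waters: list[WaterRecord] = []
    for w in model.waters:
        ox = w.oxygen
        if ox is None:
            continue
        if ox.bfactor > bfactor_max:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cv = circular_variance(ox.coords, protein_xyz, cv_radius)
        if cv >= cv_threshold:
            waters.append(
                WaterRecord(
                    coords=ox.coords.copy(),
                    bfactor=ox.bfactor,
                    circ_var=cv,
                    source_entry=model.entry_id,
                    source_chain=w.chain_id,
                )
            )

    ions: list[IonRecord] = []
    anchor_xyz = None
    if res_250 is not None:
        ch, num = _parse_res_250(res_250)
        anchor = [
            r for r in model.chains.get(ch, []) if r.seq_number == num and r.is_amino
        ]
        if anchor:
            anchor_xyz = np.array(
                [a.coords for r in anchor for a in r.atoms], dtype=float
            )
    for ion_res in model.ions:
        pos = ion_res.atoms[0].coords
        near = False
        if anchor_xyz is not None:
            near = bool(
                np.min(np.linalg.norm(anchor_xyz - pos, axis=1)) <= ION_NEAR_250_DIST
            )
        ions.append(
            IonRecord(
                element=ion_res.res_name,
                coords=pos.copy(),
                source_entry=model.entry_id,
                near_250=near,
            )
        )

    backbone = [
        ResidueCoords(
            chain_id=r.chain_id,
            seq_number=r.seq_number,
            insertion_code=r.insertion_code,
            res_name=r.res_name,
            atoms={
                a.name: a.coords.copy() for a in r.atoms if a.name in BACKBONE_ATOMS
            },
        )
        for r in protein
    ]

    res = resolution if resolution is not None else model.resolution
    if res is None:
        raise DataError(
            f"{model.entry_id}: resolution unavailable (no REMARK 2 and none supplied)"
        )
    return TemplateEntry(
        entry_id=model.entry_id,
        chain_id=chain_id,
        receptor_name=receptor_name,
        sequence=extract_sequence(model, chain_id),
        state=state,
        resolution=float(res),
        waters=waters,
        ions=ions,
        res_250=(
            res_250 if isinstance(res_250, str) or res_250 is None
            else f"{res_250[0]}:{res_250[1]}"
        ),
        backbone=backbone,
    )


def template_to_structure(
    entry: TemplateEntry, include_waters: bool = False
) -> StructureModel:
    """Rebuild a structure model from an entry's stored backbone.

    Used by leave-one-out validation: the held-out entry becomes the
    (water-stripped) query in its own coordinate frame.
    """
    from .structure_io import Atom, Residue as SioResidue

    model = StructureModel(entry_id=entry.entry_id, resolution=entry.resolution)
    for rc in entry.backbone:
        res = SioResidue(
            chain_id=rc.chain_id,
            seq_number=rc.seq_number,
            insertion_code=rc.insertion_code,
            res_name=rc.res_name,
        )
        for name in BACKBONE_ATOMS:
            if name in rc.atoms:
                element = "N" if name == "N" else ("O" if name == "O" else "C")
                res.atoms.append(
                    Atom(name=name, element=element, coords=rc.atoms[name].copy())
                )
        model.add_residue(res)
    if include_waters:
        for i, w in enumerate(entry.waters, start=1):
            res = SioResidue(
                chain_id=entry.chain_id,
                seq_number=9000 + i,
                insertion_code="",
                res_name="HOH",
            )
            res.atoms.append(
                Atom(name="O", element="O", coords=w.coords.copy(), bfactor=w.bfactor)
            )
            model.add_residue(res)
    return model


# ---------------------------------------------------------------------------
# serialisation

def _entry_to_json(e: TemplateEntry) -> dict:
    return {
        "entry_id": e.entry_id,
        "chain_id": e.chain_id,
        "receptor_name": e.receptor_name,
        "sequence": e.sequence,
        "state": e.state,
        "resolution": e.resolution,
        "res_250": e.res_250,
        "waters": [
            {
                "coords": w.coords.tolist(),
                "bfactor": w.bfactor,
                "circ_var": w.circ_var,
                "source_entry": w.source_entry,
                "source_chain": w.source_chain,
            }
            for w in e.waters
        ],
        "ions": [
            {
                "element": i.element,
                "coords": i.coords.tolist(),
                "source_entry": i.source_entry,
                "near_250": i.near_250,
            }
            for i in e.ions
        ],
        "backbone": [
            {
                "chain": rc.chain_id,
                "seq": rc.seq_number,
                "icode": rc.insertion_code,
                "resname": rc.res_name,
                "atoms": {k: v.tolist() for k, v in rc.atoms.items()},
            }
            for rc in e.backbone
        ],
    }


def _entry_from_json(d: dict) -> TemplateEntry:
    return TemplateEntry(
        entry_id=d["entry_id"],
        chain_id=d["chain_id"],
        receptor_name=d["receptor_name"],
        sequence=d["sequence"],
        state=d["state"],
        resolution=d["resolution"],
        res_250=d.get("res_250"),
        waters=[WaterRecord(**w) for w in d["waters"]],
        ions=[IonRecord(**i) for i in d["ions"]],
        backbone=[
            ResidueCoords(
                chain_id=rc["chain"],
                seq_number=rc["seq"],
                insertion_code=rc["icode"],
                res_name=rc["resname"],
                atoms=rc["atoms"],
            )
            for rc in d["backbone"]
        ],
    )


def save_db(db: ReferenceDB, path: str | Path) -> None:
    """Write the DB as JSON-lines: one header line, one entry per line."""
    path = Path(path)
    header = {
        "schema_version": db.schema_version,
        "provenance": db.provenance,
        "n_entries": len(db.entries),
    }
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "w") as fh:
        fh.write(json.dumps(header, sort_keys=True) + "\n")
        for e in db.entries:
            fh.write(json.dumps(_entry_to_json(e), sort_keys=True) + "\n")
    tmp.replace(path)


def load_db(path: str | Path) -> ReferenceDB:
    path = Path(path)
    try:
        with open(path) as fh:
            lines = [ln for ln in fh if ln.strip()]
    except OSError as exc:
        raise DataError(f"cannot read reference DB {path}: {exc}") from exc
    if not lines:
        raise DataError(f"reference DB {path} is empty")
    try:
        header = json.loads(lines[0])
        if not isinstance(header, dict):
            raise ValueError("header is not an object")
    except ValueError as exc:
        raise DataError(f"reference DB {path}: malformed header: {exc}") from exc
    version = header.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaVersionError(
            f"reference DB {path}: schema_version {version!r} "
            f"(this build reads version {SCHEMA_VERSION})"
        )
    try:
        entries = [_entry_from_json(json.loads(ln)) for ln in lines[1:]]
    except (ValueError, KeyError, TypeError) as exc:
        raise DataError(f"reference DB {path}: malformed entry: {exc}") from exc
    return ReferenceDB(
        entries=entries,
        schema_version=version,
        provenance=header.get("provenance", {}),
    )
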