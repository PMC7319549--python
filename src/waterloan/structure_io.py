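"""PDB reading/writing and the in-memory structure model.

Structures are held in a deliberately small container (chains of
residues of heavy atoms) — enough for sequence extraction, rigid-body
superposition and water bookkeeping. Parsing and serialisation are
delegated to :mod:`gemmi`; hydrogens are dropped on read and waters are
reduced to their oxygen atom, since every distance the method uses is
measured to the water oxygen.

Alternate locations: only the highest-occupancy conformer of each atom
is kept (ties resolved toward altloc ``A``). Multi-model files default
to the first model.
"""

from __future__ import annotations

import copy
import functools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import gemmi
import numpy as np

from .exceptions import ChainNotFoundError, PDBParseError

#: Residue names recognised as water.
WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})

#: Monatomic ions carried through curation (placed-ion cargo).
ION_NAMES = frozenset({"NA"})

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}


@functools.lru_cache(maxsize=None)
def _tabulated(res_name: str) -> gemmi.ResidueInfo:
    return gemmi.find_tabulated_residue(res_name)


def is_amino_acid(res_name: str) -> bool:
    """True for standard and modified amino-acid residue names."""
    if res_name in WATER_NAMES:
        return False
    info = _tabulated(res_name)
    return info is not None and info.is_amino_acid()


def one_letter(res_name: str) -> str:
    """One-letter code; modified residues map to their parent, unknown to X."""
    if res_name in AA3_TO_1:
        return AA3_TO_1[res_name]
    info = _tabulated(res_name)
    if info is not None and info.is_amino_acid():
        code = info.one_letter_code.upper()
        if code.isalpha():
            return code
    return "X"


@dataclass
class Atom:
    """One heavy atom.

    ``coords`` is a length-3 float array in Å; ``bfactor`` the isotropic
    temperature factor in Å².
    """

    name: str
    element: str
    coords: np.ndarray
    bfactor: float = 0.0
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be 3 finite numbers")
        if self.bfactor < 0:
            raise ValueError(f"atom {self.name}: negative B-factor")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy outside [0, 1]")


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    insertion_code: str
    res_name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def is_water(self) -> bool:
        return self.res_name in WATER_NAMES

    @property
    def is_amino(self) -> bool:
        return is_amino_acid(self.res_name)

    @property
    def is_hetero(self) -> bool:
        return not self.is_water and not self.is_amino

    @property
    def locator(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def oxygen(self) -> Atom | None:
        """The water oxygen (first O-element atom)."""
        for a in self.atoms:
            if a.element == "O":
                return a
        return None


@dataclass
class StructureModel:
    """A parsed structure: residues grouped by chain, plus header metadata."""

    entry_id: str = ""
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    resolution: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.resolution is not None and self.resolution <= 0:
            raise ValueError("resolution must be positive when present")

    @property
    def waters(self) -> list[Residue]:
        return [r for residues in self.chains.values() for r in residues if r.is_water]

    @property
    def ligands(self) -> list[Residue]:
        return [
            r
            for residues in self.chains.values()
            for r in residues
            if r.is_hetero and r.res_name not in ION_NAMES
        ]

    @property
    def ions(self) -> list[Residue]:
        return [
            r
            for residues in self.chains.values()
            for r in residues
            if r.res_name in ION_NAMES
        ]

    def protein_residues(self, chain_id: str | None = None) -> list[Residue]:
        if chain_id is not None:
            if chain_id not in self.chains:
                raise ChainNotFoundError(
                    f"chain {chain_id!r} not found; available: {sorted(self.chains)}"
                )
            pools = [self.chains[chain_id]]
        else:
            pools = list(self.chains.values())
        return [r for pool in pools for r in pool if r.is_amino]

    def iter_residues(self) -> Iterator[Residue]:
        for residues in self.chains.values():
            yield from residues

    def iter_atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for r in self.iter_residues():
            for a in r.atoms:
                yield r, a

    def heavy_coords(self, include_waters: bool = True) -> np.ndarray:
        """(n, 3) array of heavy-atom coordinates."""
        pts = [
            a.coords
            for r, a in self.iter_atoms()
            if include_waters or not r.is_water
        ]
        return np.asarray(pts, dtype=float).reshape(-1, 3)

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.iter_residues())

    def add_residue(self, residue: Residue) -> None:
        self.chains.setdefault(residue.chain_id, []).append(residue)

    def copy(self) -> "StructureModel":
        return copy.deepcopy(self)


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties resolve toward altloc 'A'
    return min(atoms, key=lambda a: (-a.occ, a.altloc or "A"))


def read_pdb(path: str | Path, model_index: int = 0) -> StructureModel:
    """Parse a PDB file into a :class:`StructureModel`.

    Hydrogens are skipped; altloc policy keeps the highest-occupancy
    conformer; waters are reduced to their oxygen. ``model_index``
    selects among NMR-style multi-model files (default: first).
    """
    path = Path(path)
    if not path.exists():
        raise PDBParseError(f"{path}: no such file")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise PDBParseError(f"{path}: no models with ATOM/HETATM records")
    if not 0 <= model_index < len(st):
        raise PDBParseError(
            f"{path}: model index {model_index} out of range (file has {len(st)})"
        )
    gmodel = st[model_index]
    model = StructureModel(entry_id=st.name.strip() or path.stem)
    if st.resolution and st.resolution > 0:
        model.resolution = float(st.resolution)

    n_atoms = 0
    for gchain in gmodel:
        for gres in gchain:
            groups: dict[str, list[gemmi.Atom]] = {}
            for ga in gres:
                if ga.element.is_hydrogen:
                    continue
                groups.setdefault(ga.name, []).append(ga)
            if not groups:
                continue
            res = Residue(
                chain_id=gchain.name,
                seq_number=gres.seqid.num,
                insertion_code=(gres.seqid.icode or "").strip(),
                res_name=gres.name.strip(),
            )
            for name, cands in groups.items():
                ga = _pick_altloc(cands)
                res.atoms.append(
                    Atom(
                        name=name,
                        element=ga.element.name.upper(),
                        coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        bfactor=max(float(ga.b_iso), 0.0),
                        occupancy=min(max(float(ga.occ), 0.0), 1.0),
                        altloc=(ga.altloc or "").strip("\x00 "),
                    )
                )
            if res.is_water:
                # oxygen-only representation; drop waters lacking an oxygen
                ox = res.oxygen
                if ox is None:
                    continue
                res.atoms = [ox]
            model.add_residue(res)
            n_atoms += len(res.atoms)
    if n_atoms == 0:
        raise PDBParseError(f"{path}: no heavy atoms found in model {model_index}")
    return model


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Serialise a model to PDB v3.3 text via gemmi."""
    if model.n_atoms() == 0:
        raise ValueError("refusing to write an empty model")
    st = gemmi.Structure()
    st.name = model.entry_id or "XXXX"
    if model.resolution:
        st.resolution = float(model.resolution)
    gmodel = gemmi.Model("1")
    for chain_id, residues in model.chains.items():
        gchain = gemmi.Chain(chain_id)
        for res in residues:
            gres = gemmi.Residue()
            gres.name = res.res_name
            gres.seqid = gemmi.SeqId(res.seq_number, res.insertion_code or " ")
            gres.het_flag = "A" if res.is_amino else "H"
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coords)
                ga.b_iso = a.bfactor
                ga.occ = a.occupancy
                gres.add_atom(ga)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()
    try:
        st.write_pdb(str(path))
    except (OSError, RuntimeError) as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc


def extract_sequence(model: StructureModel, chain_id: str) -> str:
    """One-letter sequence of a chain's amino-acid residues, in file order.

    Numbering gaps insert nothing; modified residues map to their parent
    amino acid (unknown ones to ``X``).
    """
    residues = model.protein_residues(chain_id)
    if not residues:
        raise ChainNotFoundError(
            f"chain {chain_id!r} has no amino-acid residues; "
            f"available chains: {sorted(model.chains)}"
        )
    return "".join(one_letter(r.res_name) for r in residues)


def strip_for_curation(
    model: StructureModel,
    keep_chain: str,
    ligand_names: frozenset[str] | set[str] = frozenset(),
) -> StructureModel:
    """Reduce a template structure to one receptor chain plus its cargo.

    Retains: amino-acid residues of ``keep_chain``; hetero residues whose
    name is in ``ligand_names`` (the receptor's own ligands); waters and
    monatomic ions that sit nearer to a kept atom than to any atom of a
    removed chain/residue. Everything else — auxiliary chains, fusion
    proteins, crystallisation additives — is dropped.
    """
    if keep_chain not in model.chains:
        raise ChainNotFoundError(
            f"chain {keep_chain!r} not found; available: {sorted(model.chains)}"
        )

    kept: list[Residue] = []
    removed: list[Residue] = []
    mobile: list[Residue] = []  # waters + ions, assigned by proximity
    for res in model.iter_residues():
        if res.is_water or res.res_name in ION_NAMES:
            mobile.append(res)
        elif res.is_amino:
            (kept if res.chain_id == keep_chain else removed).append(res)
        elif res.res_name in ligand_names:
            kept.append(res)
        else:
            removed.append(res)

    out = StructureModel(
        entry_id=model.entry_id,
        resolution=model.resolution,
        metadata=dict(model.metadata),
    )
    for res in kept:
        out.add_residue(copy.deepcopy(res))

    if mobile:
        kept_xyz = np.array(
            [a.coords for r in kept for a in r.atoms], dtype=float
        ).reshape(-1, 3)
        removed_xyz = np.array(
            [a.coords for r in removed for a in r.atoms], dtype=float
        ).reshape(-1, 3)
        for res in mobile:
            pos = res.atoms[0].coords
            if kept_xyz.size == 0:
                continue
            d_kept = np.min(np.linalg.norm(kept_xyz - pos, axis=1))
            if removed_xyz.size:
                d_removed = np.min(np.linalg.norm(removed_xyz - pos, axis=1))
                if d_removed < d_kept:
                    continue
            out.add_residue(copy.deepcopy(res))
    return out
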