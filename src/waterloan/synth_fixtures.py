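"""Synthetic homolog families with planted waters and known ground truth.

The generator emulates the ingredients the hydration method relies on:
an α-helical bundle (ideal helices, rise 1.5 Å and 100° per residue,
arranged on a circle around a central pore), waters planted on the pore
axis (internal — buried, circular variance well above the 0.6 cutoff)
and outside the bundle surface (external, CV well below the cutoff),
and a family of homologs derived from a common ancestor by seeded point
substitutions, backbone jitter and whole-body rigid motions. A
designated subset of the cavity waters is copied into every member
("conserved"); the rest are member-specific. Because the truth —
sequences, labels, conserved-water positions, rigid motions — is known
by construction, every downstream module can be tested against it.

Everything is reproducible: one integer seed determines the family
byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .exceptions import DataError
from .structure_io import AA1_TO_3, AA3_TO_1, Atom, Residue, StructureModel, write_pdb
from .water_db import (
    ReferenceDB,
    TemplateEntry,
    build_template_entry,
    circular_variance,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# ideal alpha-helix: rise per residue and rotation per residue
HELIX_RISE = 1.5  # Å
HELIX_TWIST = 100.0  # degrees
# backbone atom offsets in helix cylindrical coordinates:
# (radius Å, phase offset deg, z offset Å) relative to the residue's CA
ATOM_OFFSETS = {
    "N": (1.60, -26.0, -0.90),
    "CA": (2.30, 0.0, 0.00),
    "C": (1.70, 21.0, 0.70),
    "O": (2.05, 39.0, 1.20),
}
MIN_HELIX_SPACING = 9.5  # Å between neighbouring helix axes

WATER_SPACING = 3.2  # Å between planted pore waters
WATER_PROTEIN_MIN = 3.0  # Å planted-water to protein floor
SURFACE_MARGIN = 4.5  # Å outside the outermost protein atom
CV_INTERNAL_MARGIN = 0.7  # planted internal waters must reach this CV
CV_EXTERNAL_MARGIN = 0.5  # planted external waters must stay below this


@dataclass
class FixtureSpec:
    """Parameters of one synthetic family."""

    seed: int = 0
    n_helices: int = 7
    helix_length: int = 36
    family_size: int = 6
    target_identity: float = 90.0  # % identity of each member to the ancestor
    n_cavity_waters: int = 8
    n_surface_waters: int = 4
    coordinate_noise: float = 0.3  # Å backbone jitter between members
    bfactor_range: tuple[float, float] = (5.0, 40.0)
    n_conserved: int | None = None  # None → all cavity waters conserved
    plant_sodium: bool = False
    states: tuple[str, ...] = ("inactive", "active")

    def __post_init__(self) -> None:
        if not 0 < self.target_identity <= 100:
            raise ValueError("target_identity must be in (0, 100]")
        if min(self.n_cavity_waters, self.n_surface_waters) < 0:
            raise ValueError("water counts must be non-negative")
        if self.coordinate_noise < 0:
            raise ValueError("coordinate_noise must be non-negative")


@dataclass
class FamilyMember:
    model: StructureModel
    metadata: dict
    rotation: np.ndarray
    translation: np.ndarray
    conserved_coords: np.ndarray  # (n_conserved, 3), member frame
    water_labels: list[str] = field(default_factory=list)
    sequence: str = ""


def _bundle_radius(n_helices: int) -> float:
    return max(7.8, MIN_HELIX_SPACING / (2.0 * math.sin(math.pi / n_helices)))


def generate_bundle(spec: FixtureSpec) -> StructureModel:
    """Ideal parallel α-helical bundle with a central pore.

    One chain (``A``), residues numbered continuously across helices,
    full backbone (N, Cα, C, O), random sequence from the seeded
    generator. Deterministic for a fixed seed.
    """
    if spec.n_helices < 3:
        raise DataError("need at least 3 helices to enclose a pore")
    if spec.helix_length < 5:
        raise DataError("helix_length too short for a meaningful bundle")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    n_res = spec.n_helices * spec.helix_length
    sequence = "".join(rng.choice(list(AA20), size=n_res))
    rb = _bundle_radius(spec.n_helices)

    model = StructureModel(entry_id=f"SYN-{spec.seed}", metadata={"seed": spec.seed})
    res_num = 0
    for h in range(spec.n_helices):
        alpha = 2.0 * math.pi * h / spec.n_helices
        cx, cy = rb * math.cos(alpha), rb * math.sin(alpha)
        phase0 = math.degrees(alpha) + 180.0
        for i in range(spec.helix_length):
            res_num += 1
            aa1 = sequence[res_num - 1]
            res = Residue(
                chain_id="A",
                seq_number=res_num,
                insertion_code="",
                res_name=AA1_TO_3[aa1],
            )
            theta = phase0 + i * HELIX_TWIST
            z0 = i * HELIX_RISE
            for name, (r, dphi, dz) in ATOM_OFFSETS.items():
                ang = math.radians(theta + dphi)
                pos = np.array(
                    [cx + r * math.cos(ang), cy + r * math.sin(ang), z0 + dz]
                )
                element = "N" if name == "N" else ("O" if name == "O" else "C")
                res.atoms.append(
                    Atom(name=name, element=element, coords=pos, bfactor=20.0)
                )
            model.add_residue(res)
    return model


def _protein_xyz(model: StructureModel) -> np.ndarray:
    return np.array(
        [a.coords for r, a in model.iter_atoms() if r.is_amino], dtype=float
    ).reshape(-1, 3)


def plan_water_sites(
    model: StructureModel, spec: FixtureSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Choose cavity (pore-axis) and surface water positions.

    Cavity waters sit on the pore axis, ≥ ``WATER_SPACING`` apart and
    well separated from the protein, with CV at least
    ``CV_INTERNAL_MARGIN``; surface waters sit ≥ 4 Å outside the
    outermost protein atom with CV at most ``CV_EXTERNAL_MARGIN``.
    """
    prot = _protein_xyz(model)
    z_lo, z_hi = prot[:, 2].min(), prot[:, 2].max()
    height = z_hi - z_lo

    cavity = []
    if spec.n_cavity_waters:
        span = (spec.n_cavity_waters - 1) * WATER_SPACING
        z_start = z_lo + height / 2.0 - span / 2.0
        if z_start < z_lo + 0.15 * height or z_start + span > z_lo + 0.85 * height:
            raise DataError(
                f"cavity too small for {spec.n_cavity_waters} waters "
                f"(bundle height {height:.1f} Å)"
            )
        for i in range(spec.n_cavity_waters):
            base = np.array(
                [0.0, 0.0, z_start + i * WATER_SPACING]
            )
            for attempt in range(10):
                pos = base + np.append(rng.uniform(-0.3, 0.3, size=2), 0.0)
                d_prot = np.min(np.linalg.norm(prot - pos, axis=1))
                cv = circular_variance(pos, prot)
                if d_prot >= WATER_PROTEIN_MIN and cv >= CV_INTERNAL_MARGIN:
                    cavity.append(pos)
                    break
            else:
                raise DataError("could not place a cavity water with CV margin")

    r_out = np.max(np.linalg.norm(prot[:, :2], axis=1)) + SURFACE_MARGIN
    surface = []
    for _ in range(spec.n_surface_waters):
        az = rng.uniform(0.0, 2.0 * math.pi)
        z = rng.uniform(z_lo + 0.2 * height, z_lo + 0.8 * height)
        radius = r_out
        for attempt in range(10):
            pos = np.array([radius * math.cos(az), radius * math.sin(az), z])
            d_prot = np.min(np.linalg.norm(prot - pos, axis=1))
            cv = circular_variance(pos, prot)
            if d_prot >= 4.0 and cv <= CV_EXTERNAL_MARGIN:
                surface.append(pos)
                break
            radius += 1.0
        else:
            raise DataError("could not place a surface water with CV margin")
    return (
        np.asarray(cavity, dtype=float).reshape(-1, 3),
        np.asarray(surface, dtype=float).reshape(-1, 3),
    )


def plant_waters(
    model: StructureModel, spec: FixtureSpec
) -> tuple[StructureModel, list[str], np.ndarray]:
    """Plant cavity + surface waters into a bundle.

    Returns (model copy with waters, truth labels aligned with the
    waters, their coordinates). B-factors are sampled uniformly from
    ``spec.bfactor_range``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    cavity, surface = plan_water_sites(model, spec, rng)
    out = model.copy()
    labels: list[str] = []
    coords: list[np.ndarray] = []
    serial = 0
    for pos, label in [(p, "internal") for p in cavity] + [
        (p, "external") for p in surface
    ]:
        serial += 1
        res = Residue(
            chain_id="A",
            seq_number=1000 + serial,
            insertion_code="",
            res_name="HOH",
        )
        b = float(rng.uniform(*spec.bfactor_range))
        res.atoms.append(Atom(name="O", element="O", coords=pos, bfactor=b))
        out.add_residue(res)
        labels.append(label)
        coords.append(pos)
    return out, labels, np.asarray(coords, dtype=float).reshape(-1, 3)


def _mutate(
    sequence: str,
    pool: np.ndarray,
    rng: np.random.Generator,
) -> str:
    chars = list(sequence)
    for pos in pool:
        old = chars[pos]
        alternatives = [a for a in AA20 if a != old]
        chars[pos] = str(rng.choice(alternatives))
    return "".join(chars)


def _res_250_index(spec: FixtureSpec) -> int:
    # middle of the second helix, 0-based residue index
    return spec.helix_length + spec.helix_length // 2


def generate_family(spec: FixtureSpec) -> list[FamilyMember]:
    """Derive ``family_size`` homologs from a common ancestor.

    Substituted positions are drawn once for the whole family, so each
    member sits at ``target_identity`` % to the ancestor and members
    stay close to that identity pairwise. Backbones are jittered by
    ``coordinate_noise`` and each member receives its own random rigid
    motion, so superposition is non-trivial. Conserved cavity waters are
    copied (jittered) into every member; remaining cavity waters are
    assigned round-robin to single members.
    """
    if spec.family_size < 2:
        raise DataError("family_size must be at least 2")
    ancestor = generate_bundle(spec)
    rng_fam = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    _, labels, coords = plant_waters(ancestor, spec)
    cavity = coords[[i for i, l in enumerate(labels) if l == "internal"]]
    surface = coords[[i for i, l in enumerate(labels) if l == "external"]]
    n_cons = spec.n_conserved if spec.n_conserved is not None else len(cavity)
    if not 0 <= n_cons <= len(cavity):
        raise DataError("n_conserved exceeds the number of cavity waters")
    conserved = cavity[:n_cons]
    specific = cavity[n_cons:]

    anc_seq = "".join(AA3_TO_1[r.res_name] for r in ancestor.protein_residues("A"))
    length = len(anc_seq)
    n_mut = round(length * (1.0 - spec.target_identity / 100.0))
    if n_mut > length:
        raise DataError("identity target unreachable")
    pool = rng_fam.choice(length, size=n_mut, replace=False) if n_mut else np.array([], dtype=int)

    members: list[FamilyMember] = []
    children = np.random.SeedSequence([spec.seed, 3]).spawn(spec.family_size)
    for m in range(spec.family_size):
        rng = np.random.default_rng(children[m])
        seq_m = _mutate(anc_seq, pool, rng)
        rot = Rotation.random(random_state=rng).as_matrix()
        trans = rng.uniform(-15.0, 15.0, size=3)

        def move(p: np.ndarray) -> np.ndarray:
            return p @ rot.T + trans

        model = StructureModel(
            entry_id=f"SYN{m}",
            resolution=round(1.8 + 0.1 * m, 2),
            metadata={"seed": spec.seed, "member": m},
        )
        for idx, res in enumerate(ancestor.protein_residues("A")):
            new = Residue(
                chain_id="A",
                seq_number=res.seq_number,
                insertion_code="",
                res_name=AA1_TO_3[seq_m[idx]],
            )
            for a in res.atoms:
                jitter = rng.normal(0.0, spec.coordinate_noise, size=3)
                new.atoms.append(
                    Atom(
                        name=a.name,
                        element=a.element,
                        coords=move(a.coords + jitter),
                        bfactor=a.bfactor,
                    )
                )
            model.add_residue(new)

        # member protein coordinates before the rigid motion (CV is
        # rigid-invariant, so margins checked here hold in the output)
        member_prot = np.array(
            [
                a.coords
                for r, a in model.iter_atoms()
                if r.is_amino
            ],
            dtype=float,
        )
        inv_rot, inv_t = rot.T, -rot.T @ trans
        member_prot_local = member_prot @ inv_rot.T + inv_t

        def jittered_internal(p: np.ndarray) -> np.ndarray:
            # re-draw the jitter until the emitted water keeps the
            # internal CV margin in the member's own backbone frame
            for _ in range(50):
                cand = p + rng.normal(0.0, spec.coordinate_noise, size=3)
                if circular_variance(cand, member_prot_local) >= CV_INTERNAL_MARGIN:
                    return move(cand)
            raise DataError("conserved water lost its internal CV margin")

        def jittered_external(p: np.ndarray) -> np.ndarray:
            for _ in range(50):
                cand = p + rng.normal(0.0, spec.coordinate_noise, size=3)
                if circular_variance(cand, member_prot_local) <= CV_EXTERNAL_MARGIN:
                    return move(cand)
            raise DataError("surface water lost its external CV margin")

        water_positions: list[np.ndarray] = []
        water_labels: list[str] = []
        for p in conserved:
            water_positions.append(jittered_internal(p))
            water_labels.append("internal")
        for j, p in enumerate(specific):
            if j % spec.family_size == m:
                water_positions.append(jittered_internal(p))
                water_labels.append("internal")
        for p in surface:
            water_positions.append(jittered_external(p))
            water_labels.append("external")
        for i, pos in enumerate(water_positions, start=1):
            res = Residue(
                chain_id="A", seq_number=1000 + i, insertion_code="", res_name="HOH"
            )
            b = float(rng.uniform(*spec.bfactor_range))
            res.atoms.append(Atom(name="O", element="O", coords=pos, bfactor=b))
            model.add_residue(res)

        res_250 = ""
        if spec.plant_sodium:
            anchor = ancestor.protein_residues("A")[_res_250_index(spec)]
            ca = anchor.atom("CA").coords
            radial = np.linalg.norm(ca[:2])
            # walk inward from the 2.50 CA until the site has enough
            # clearance from the member backbone to survive the 1.8 Å rule
            # the member's own (jittered) anchor atoms, in the local frame —
            # exactly what DB curation will measure the ion against
            idx = _res_250_index(spec)
            anchor_xyz = member_prot_local[4 * idx : 4 * idx + 4]
            # best-cleared site on the inward path that still counts as
            # "near" the 2.50 residue for DB curation
            best_clear, inward = -np.inf, None
            for s in np.arange(3.0, 7.25, 0.25):
                for dz in np.arange(-2.0, 2.25, 0.5):
                    cand = np.array(
                        [
                            ca[0] * (1 - s / radial),
                            ca[1] * (1 - s / radial),
                            ca[2] + dz,
                        ]
                    )
                    clearance = np.min(
                        np.linalg.norm(member_prot_local - cand, axis=1)
                    )
                    near_anchor = np.min(np.linalg.norm(anchor_xyz - cand, axis=1))
                    if near_anchor <= 5.5 and clearance > best_clear:
                        best_clear, inward = clearance, cand
            if inward is None or best_clear < 2.7:
                raise DataError("no sodium site with enough backbone clearance")
            ion = Residue(
                chain_id="A", seq_number=3001, insertion_code="", res_name="NA"
            )
            ion.atoms.append(Atom(name="NA", element="NA", coords=move(inward)))
            model.add_residue(ion)
            res_250 = f"A:{anchor.seq_number}"

        n_cons_here = len(conserved)
        members.append(
            FamilyMember(
                model=model,
                metadata={
                    "entry_id": f"SYN{m}",
                    "chain": "A",
                    "receptor_name": f"REC{m}",
                    "state": spec.states[m % len(spec.states)],
                    "resolution": model.resolution,
                    "res_250": res_250,
                },
                rotation=rot,
                translation=trans,
                conserved_coords=np.asarray(
                    water_positions[:n_cons_here], dtype=float
                ).reshape(-1, 3),
                water_labels=water_labels,
                sequence=seq_m,
            )
        )
    return members


def family_reference_db(
    members: list[FamilyMember], **curation_kwargs
) -> ReferenceDB:
    """Curate a generated family straight into a reference DB."""
    entries: list[TemplateEntry] = []
    for fm in members:
        entries.append(
            build_template_entry(
                fm.model,
                receptor_name=fm.metadata["receptor_name"],
                state=fm.metadata["state"],
                res_250=fm.metadata["res_250"] or None,
                chain_id=fm.metadata["chain"],
                resolution=fm.metadata["resolution"],
                **curation_kwargs,
            )
        )
    return ReferenceDB(entries=entries, provenance={"generator": "synth_fixtures"})


def write_fixture_dir(members: list[FamilyMember], out_dir: str | Path) -> Path:
    """Write member PDBs plus the sidecar metadata TSV for DB building."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = ["entry_id\tchain\treceptor_name\tstate\tresolution\tres_250\tfile"]
    for fm in members:
        fname = f"{fm.metadata['entry_id']}.pdb"
        write_pdb(fm.model, out_dir / fname)
        rows.append(
            "\t".join(
                [
                    fm.metadata["entry_id"],
                    fm.metadata["chain"],
                    fm.metadata["receptor_name"],
                    fm.metadata["state"],
                    str(fm.metadata["resolution"]),
                    fm.metadata["res_250"],
                    fname,
                ]
            )
        )
    meta = out_dir / "metadata.tsv"
    meta.write_text("\n".join(rows) + "\n")
    return meta
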