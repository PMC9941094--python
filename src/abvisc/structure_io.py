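"""Protein structure input, parameter assignment, and segment annotation.

Structures are read from standard PDB files (via gemmi), partial charges and
van der Waals radii come from a bundled minimal parameter table that localizes
formal charges on the ionizable side-chain groups (Asp/Glu carboxylates, Lys
amine, Arg guanidine, optionally His and the chain termini) and places a small
internally-neutral dipole on the backbone.  This preserves the sign structure
of the electrostatic surface without requiring a full force field.
"""

from __future__ import annotations

import copy
import importlib.resources
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import gemmi
import numpy as np
import yaml

from .errors import (
    AnnotationError,
    EmptyStructureError,
    FormatError,
    ParameterizationError,
)

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

AROMATIC_RESIDUES = {"HIS", "PHE", "TYR", "TRP"}
CARBOXYLATE_ATOMS = {"ASP": ("CG", "OD1", "OD2"), "GLU": ("CD", "OE1", "OE2")}
CATION_ATOMS = {"LYS": ("NZ",), "ARG": ("NE", "CZ", "NH1", "NH2")}


def _load_yaml(name: str) -> dict:
    ref = importlib.resources.files("abvisc.data").joinpath(name)
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


@lru_cache(maxsize=None)
def load_parameter_table(table: str = "default") -> dict:
    if table != "default":
        raise ParameterizationError(f"unknown parameter table {table!r}")
    return _load_yaml("charges.yaml")


@lru_cache(maxsize=None)
def load_scales() -> dict:
    return _load_yaml("scales.yaml")


@lru_cache(maxsize=None)
def load_chothia_ranges() -> dict:
    return _load_yaml("chothia_cdr.yaml")


@dataclass
class Atom:
    """A single atom with coordinates and (optionally assigned) parameters."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    insertion_code: str
    chain_id: str
    position: np.ndarray  # (3,) Angstrom
    partial_charge: float = np.nan
    radius: float = np.nan
    mass: float = np.nan

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"


@dataclass
class Structure:
    """An ordered list of atoms plus chain roles and a provenance log."""

    atoms: list[Atom]
    chains: dict[str, str] = field(default_factory=dict)  # chain_id -> role
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.atoms:
            raise EmptyStructureError("structure has no atoms")

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms], dtype=float)

    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    def has_hydrogens(self) -> bool:
        return any(a.is_hydrogen for a in self.atoms)

    def residues(self) -> list[tuple[tuple[str, int, str], list[Atom]]]:
        """Residues in atom order as (key, atoms) pairs."""
        out: list[tuple[tuple[str, int, str], list[Atom]]] = []
        index: dict[tuple[str, int, str], int] = {}
        for a in self.atoms:
            k = a.residue_key
            if k not in index:
                index[k] = len(out)
                out.append((k, []))
            out[index[k]][1].append(a)
        return out

    def heavy_atom_indices(self) -> np.ndarray:
        return np.array(
            [i for i, a in enumerate(self.atoms) if not a.is_hydrogen], dtype=int
        )

    def copy(self) -> "Structure":
        return copy.deepcopy(self)

    def center_of_mass(self) -> np.ndarray:
        m = self.masses()
        if np.any(np.isnan(m)):
            raise ParameterizationError("masses not assigned; run assign_parameters")
        return (self.coords() * m[:, None]).sum(axis=0) / m.sum()


@dataclass
class SegmentMap:
    """Per-residue framework/CDR labels."""

    labels: dict[tuple[str, int, str], str]

    def label_of(self, key: tuple[str, int, str]) -> str:
        return self.labels.get(key, "unknown")


def _infer_role(chain_id: str) -> str:
    cid = chain_id.upper()
    if cid in ("H", "B"):
        return "heavy"
    if cid in ("L", "A", "K"):
        return "light"
    return "other"


def read_pdb(path: str | Path, keep_hetero: bool = False) -> Structure:
    """Read a PDB file into a Structure.

    Waters and (by default) hetero groups are dropped; hydrogens are kept if
    present.  Chain roles are inferred from chain id (H -> heavy, L -> light,
    else other) and can be overridden on ``Structure.chains``.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    atoms: list[Atom] = []
    chains: dict[str, str] = {}
    if len(st) == 0:
        raise EmptyStructureError(f"{path} contains no models")
    model = st[0]
    for chain in model:
        for res in chain:
            if res.name in _WATER_NAMES:
                continue
            if res.het_flag == "H" and not keep_hetero:
                continue
            for at in res:
                atoms.append(
                    Atom(
                        serial=at.serial,
                        name=at.name,
                        element=at.element.name,
                        residue_name=res.name,
                        residue_number=res.seqid.num,
                        insertion_code=(res.seqid.icode or "").strip(),
                        chain_id=chain.name,
                        position=np.array(
                            [at.pos.x, at.pos.y, at.pos.z], dtype=float
                        ),
                    )
                )
            chains.setdefault(chain.name, _infer_role(chain.name))
    if not atoms:
        raise EmptyStructureError(f"{path}: no protein atoms after filtering")
    return Structure(atoms=atoms, chains=chains, provenance=[f"read_pdb:{path}"])


def write_pdb(s: Structure, path: str | Path) -> None:
    """Write a Structure to a PDB file (coordinates at 1e-3 A precision)."""
    st = gemmi.Structure()
    st.name = "abvisc"
    model = gemmi.Model("1")
    chain_map: dict[str, gemmi.Chain] = {}
    for a in s.atoms:
        ch = chain_map.get(a.chain_id)
        if ch is None:
            ch = gemmi.Chain(a.chain_id)
            chain_map[a.chain_id] = ch
        if (
            len(ch) == 0
            or ch[-1].seqid.num != a.residue_number
            or ch[-1].name != a.residue_name
        ):
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_number, a.insertion_code or " ")
            ch.add_residue(res)
        res = ch[-1]
        at = gemmi.Atom()
        at.name = a.name
        at.serial = a.serial
        at.element = gemmi.Element(a.element)
        at.pos = gemmi.Position(*a.position)
        res.add_atom(at)
    for ch in chain_map.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def assign_parameters(
    s: Structure,
    table: str = "default",
    his_charged: bool = False,
    charged_termini: bool = False,
    fallback: bool = True,
) -> Structure:
    """Assign partial charges, radii and masses from the bundled table.

    Returns a new Structure.  Unknown residues get zero charge and element
    radii when ``fallback`` is true, else raise ``ParameterizationError``.
    Per-residue charges sum exactly to the residue formal charge.
    """
    tab = load_parameter_table(table)
    known = set(load_scales()["eisenberg"])
    backbone = tab["backbone"]
    sidechain = dict(tab["sidechain"])
    if his_charged:
        sidechain["HIS"] = tab["his_plus"]
    radii = tab["radii"] if s.has_hydrogens() else tab["radii_united"]
    masses = tab["masses"]
    out = s.copy()

    residues = out.residues()
    chain_first: dict[str, tuple] = {}
    chain_last: dict[str, tuple] = {}
    for key, _ in residues:
        chain_first.setdefault(key[0], key)
        chain_last[key[0]] = key

    for key, atoms in residues:
        resname = atoms[0].residue_name
        if resname not in known:
            if not fallback:
                raise ParameterizationError(
                    f"residue {resname} {key} not in parameter table"
                )
        names = {a.name for a in atoms}
        charge_map: dict[str, float] = {}
        if resname in known:
            # backbone dipole applied pairwise so a partial backbone stays neutral
            if "N" in names and "CA" in names:
                charge_map["N"] = backbone["N"]
                charge_map["CA"] = backbone["CA"]
            if "C" in names and "O" in names:
                charge_map["C"] = backbone["C"]
                charge_map["O"] = backbone["O"]
            for k, v in sidechain.get(resname, {}).items():
                if k in names:
                    charge_map[k] = charge_map.get(k, 0.0) + v
        if charged_termini and resname in known:
            if key == chain_first[key[0]] and "N" in names:
                charge_map["N"] = charge_map.get("N", 0.0) + tab["termini"]["n_term"]["N"]
            if key == chain_last[key[0]]:
                if "OXT" in names:
                    charge_map["OXT"] = charge_map.get("OXT", 0.0) - 0.5
                    charge_map["O"] = charge_map.get("O", 0.0) - 0.5
                elif "O" in names:
                    charge_map["O"] = charge_map.get("O", 0.0) - 1.0
        for a in atoms:
            a.partial_charge = charge_map.get(a.name, 0.0)
            el = a.element.upper()
            a.radius = radii.get(el, radii["default"])
            a.mass = masses.get(el, masses["default"])
    out.provenance.append(
        f"assign_parameters:table={table},his_charged={his_charged},"
        f"charged_termini={charged_termini}"
    )
    return out


def residue_formal_charge(
    resname: str,
    his_charged: bool = False,
) -> float:
    """Formal charge convention used by the bundled table."""
    tab = load_parameter_table()
    fc = dict(tab["formal_charges"])
    if his_charged:
        fc["HIS"] = 1.0
    return fc.get(resname, 0.0)


def canonicalize(s: Structure) -> Structure:
    """Translate the structure so its center of mass is at the origin."""
    com = s.center_of_mass()
    out = s.copy()
    for a in out.atoms:
        a.position = a.position - com
    out.provenance.append(f"canonicalize:translate={(-com).tolist()}")
    return out


def annotate_segments(
    s: Structure,
    numbering: dict[tuple[str, int, str], int] | None = None,
    ranges: dict | None = None,
) -> SegmentMap:
    """Label each residue framework / CDR-x / unknown.

    ``numbering`` maps residue keys to Chothia positions; when absent every
    residue is labeled unknown.  Chains with role ``other`` are always
    unknown.  Missing numbers for heavy/light residues raise AnnotationError.
    """
    if ranges is None:
        ranges = load_chothia_ranges()
    labels: dict[tuple[str, int, str], str] = {}
    if numbering is None:
        for key, _ in s.residues():
            labels[key] = "unknown"
        return SegmentMap(labels)
    missing = []
    for key, _ in s.residues():
        role = s.chains.get(key[0], "other")
        if role not in ("heavy", "light"):
            labels[key] = "unknown"
            continue
        if key not in numbering:
            missing.append(key)
            continue
        num = numbering[key]
        table = ranges["heavy"] if role == "heavy" else ranges["light"]
        label = "framework"
        for cdr, (lo, hi) in table.items():
            if lo <= num <= hi:
                label = cdr
                break
        labels[key] = label
    if missing:
        raise AnnotationError(f"numbering missing for residues: {missing}")
    return SegmentMap(labels)
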