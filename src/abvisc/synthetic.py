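"""Synthetic pseudo-protein structures with controllable charge patches.

The generator places residues on a spherical scaffold with side chains
pointing outward, so charged groups are solvent-exposed and form surface
patches of controllable size.  Labels emulate the causal structure the
viscosity model assumes: log10(viscosity) is an affine function of the
negative electrostatic surface-patch area (computed by this package's own
SES/ESP pipeline) plus Gaussian noise.  Side-chain geometry is slightly
compressed relative to real rotamers so the largest toys fit the desk-scale
+-12 Angstrom grid; every residue uses real names and atom names so charge
assignment, Eisenberg classification and patch composition all work
unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .pipeline import FeaturizeConfig, featurize_structure
from .structure_io import Atom, Structure, assign_parameters, canonicalize
from .surface import DESK_GRID, GridSpec

#: featurization profile used for desk-scale studies and tests.  Screening
#: at physiological ionic strength (Debye length ~8 A) keeps the ESP of a
#: charge patch local on the +-12 A toy grid; without it every voxel of a
#: 4 A-radius toy sits in the monopole far field and "patch area" loses its
#: meaning as a local surface feature.
DESK_FEATURIZE = FeaturizeConfig(grid=DESK_GRID, solver="fd_pb", ionic_strength=0.15)

# outward side-chain templates: (atom name, radial step, tangential offset)
_SIDECHAINS: dict[str, list[tuple[str, float, float]]] = {
    "GLY": [],
    "ALA": [("CB", 1.3, 0.0)],
    "SER": [("CB", 1.3, 0.0), ("OG", 2.4, 0.3)],
    "LEU": [("CB", 1.2, 0.0), ("CG", 2.2, 0.0), ("CD1", 3.0, 0.7), ("CD2", 3.0, -0.7)],
    "PHE": [
        ("CB", 1.2, 0.0), ("CG", 2.2, 0.0), ("CD1", 2.9, 0.9), ("CD2", 2.9, -0.9),
        ("CE1", 3.7, 0.9), ("CE2", 3.7, -0.9), ("CZ", 4.1, 0.0),
    ],
    "TYR": [
        ("CB", 1.2, 0.0), ("CG", 2.2, 0.0), ("CD1", 2.9, 0.9), ("CD2", 2.9, -0.9),
        ("CE1", 3.7, 0.9), ("CE2", 3.7, -0.9), ("CZ", 4.1, 0.0), ("OH", 4.7, 0.0),
    ],
    "ASP": [("CB", 1.2, 0.0), ("CG", 2.3, 0.0), ("OD1", 3.1, 0.8), ("OD2", 3.1, -0.8)],
    "GLU": [
        ("CB", 1.1, 0.0), ("CG", 2.0, 0.0), ("CD", 2.9, 0.0),
        ("OE1", 3.6, 0.8), ("OE2", 3.6, -0.8),
    ],
    "LYS": [
        ("CB", 0.9, 0.0), ("CG", 1.7, 0.0), ("CD", 2.5, 0.0),
        ("CE", 3.4, 0.0), ("NZ", 4.2, 0.0),
    ],
    "ARG": [
        ("CB", 0.9, 0.0), ("CG", 1.7, 0.0), ("CD", 2.5, 0.0), ("NE", 3.2, 0.0),
        ("CZ", 3.9, 0.0), ("NH1", 4.4, 0.7), ("NH2", 4.4, -0.7),
    ],
}


@dataclass(frozen=True)
class PatchSpec:
    """A surface patch: the ``count`` residues nearest ``direction`` become
    ``residue`` (e.g. ASP for a negative patch, LYS for a cation patch)."""

    direction: tuple[float, float, float]
    count: int
    residue: str = "ASP"


@dataclass(frozen=True)
class ToySpec:
    n_residues: int = 32
    radius: float = 4.0  # scaffold sphere radius, Angstrom
    patches: tuple[PatchSpec, ...] = ()
    filler: tuple[str, ...] = ("SER", "LEU", "GLY")
    jitter: float = 0.12  # coordinate noise, Angstrom
    seed: int = 0


@dataclass(frozen=True)
class LabelModel:
    """log10(viscosity/cP) = intercept + slope * driver (+ noise)."""

    slope: float = 0.6
    intercept: float = 1.0
    noise_sd: float = 0.15  # log10-cP
    driver: str = "negative_patch_area"  # negative_patch_area | scm_score
    esp_threshold: float = -1.0  # kT/e: shell voxels below this count as area
    standardize: bool = True


@dataclass
class LabeledStructure:
    structure_id: str
    structure: Structure
    viscosity_cP: float
    driver_value: float


def _fibonacci_directions(n: int) -> np.ndarray:
    k = np.arange(n)
    golden = math.pi * (3.0 - math.sqrt(5.0))
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    th = golden * k
    return np.stack([r * np.cos(th), r * np.sin(th), z], axis=1)


def _tangent_frame(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([1.0, 0.0, 0.0])
    if abs(u @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    t1 = np.cross(u, a)
    t1 /= np.linalg.norm(t1)
    return t1, np.cross(u, t1)


def make_toy_structure(spec: ToySpec) -> Structure:
    """Deterministic compact pseudo-protein on a spherical scaffold."""
    if spec.n_residues < 2:
        raise DataError("need at least 2 residues")
    total_patch = sum(p.count for p in spec.patches)
    if total_patch > spec.n_residues:
        raise DataError("patch residues exceed scaffold size")
    rng = np.random.default_rng(spec.seed)
    dirs = _fibonacci_directions(spec.n_residues)

    resnames = [None] * spec.n_residues
    for patch in spec.patches:
        if patch.residue not in _SIDECHAINS:
            raise DataError(f"no template for residue {patch.residue}")
        center = np.asarray(patch.direction, float)
        center = center / np.linalg.norm(center)
        order = np.argsort(-(dirs @ center))
        placed = 0
        for i in order:
            if placed == patch.count:
                break
            if resnames[i] is None:
                resnames[i] = patch.residue
                placed += 1
        if placed < patch.count:
            raise DataError("infeasible packing: overlapping patches")
    fill = 0
    for i in range(spec.n_residues):
        if resnames[i] is None:
            resnames[i] = spec.filler[fill % len(spec.filler)]
            fill += 1

    atoms: list[Atom] = []
    serial = 1
    half = spec.n_residues // 2
    chain_res_counter = {"L": 0, "H": 0}
    for i, (u, resname) in enumerate(zip(dirs, resnames)):
        chain = "L" if i < half else "H"
        chain_res_counter[chain] += 1
        resnum = chain_res_counter[chain]
        t1, t2 = _tangent_frame(u)
        ca = spec.radius * u
        backbone = [
            ("N", ca - 1.45 * t1),
            ("CA", ca),
            ("C", ca + 1.45 * t1),
            ("O", ca + 1.45 * t1 + 1.23 * t2),
        ]
        side = [
            (name, ca + step * u + off * t2)
            for name, step, off in _SIDECHAINS[resname]
        ]
        for name, pos in backbone + side:
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element=name[0],
                    residue_name=resname,
                    residue_number=resnum,
                    insertion_code="",
                    chain_id=chain,
                    position=pos + rng.normal(0.0, spec.jitter, 3),
                )
            )
            serial += 1
    s = Structure(
        atoms=atoms,
        chains={"L": "light", "H": "heavy"},
        provenance=[f"make_toy_structure:seed={spec.seed}"],
    )
    return s


def negative_patch_area(
    s: Structure,
    cfg: FeaturizeConfig = DESK_FEATURIZE,
    esp_threshold: float = -1.0,
) -> float:
    """Number of surface-shell voxels with ESP below ``esp_threshold`` —
    the package's own measure of negative electrostatic patch area."""
    grid = featurize_structure(s, cfg)
    return float(np.sum(grid.channels[0] < esp_threshold))


def make_labeled_dataset(
    n: int,
    label_model: LabelModel = LabelModel(),
    seed: int = 0,
    featurize_cfg: FeaturizeConfig = DESK_FEATURIZE,
    max_negative: int = 10,
    n_cations: int = 2,
) -> list[LabeledStructure]:
    """``n`` toy structures with graded negative-patch sizes and labels
    generated from the configured driver plus Gaussian log-scale noise."""
    if n < 4:
        raise DataError("need at least 4 structures")
    rng = np.random.default_rng(seed)
    records: list[LabeledStructure] = []
    for i in range(n):
        n_neg = int(round(max_negative * i / (n - 1)))
        patches = []
        if n_neg:
            patches.append(PatchSpec(direction=(0.0, 0.0, 1.0), count=n_neg))
        if n_cations:
            patches.append(
                PatchSpec(direction=(0.0, 0.0, -1.0), count=n_cations, residue="LYS")
            )
        toy = ToySpec(patches=tuple(patches), seed=seed + 1000 + i)
        s = canonicalize(assign_parameters(make_toy_structure(toy)))
        if label_model.driver == "negative_patch_area":
            driver = negative_patch_area(
                s, featurize_cfg, label_model.esp_threshold
            )
        elif label_model.driver == "scm_score":
            from .baselines import scm_score

            driver = scm_score(s, spec=featurize_cfg.grid).score
        else:
            raise DataError(f"unknown driver {label_model.driver!r}")
        records.append(LabeledStructure(f"toy{i:03d}", s, np.nan, driver))

    d = np.array([r.driver_value for r in records])
    if label_model.standardize:
        sd = d.std()
        z = (d - d.mean()) / (sd if sd > 0 else 1.0)
    else:
        z = d
    noise = rng.normal(0.0, label_model.noise_sd, n) if label_model.noise_sd else 0.0
    log_eta = label_model.intercept + label_model.slope * z + noise
    for r, v in zip(records, 10.0**log_eta):
        r.viscosity_cP = float(v)
    return records
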