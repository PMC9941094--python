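"""Integrated-gradients attribution and surface-patch analysis.

Attribution scores are the straight-line path integral of the model gradient
from an all-zero baseline to the input, evaluated with a midpoint Riemann
rule; by the completeness axiom the scores sum to F(x) - F(baseline).
Significant voxels (|score| above one standard deviation of the pooled
nonzero scores of a test set) are grouped into contiguous patches linked at
1.5 Angstrom (twice the full-scale grid resolution), and patches are
decomposed by biophysical category and antibody segment of the nearest
protein heavy atom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .errors import ConfigError, DegenerateError
from .fields import InputGrid
from .network import Cnn3d
from .structure_io import (
    AROMATIC_RESIDUES,
    CARBOXYLATE_ATOMS,
    CATION_ATOMS,
    SegmentMap,
    Structure,
)
from .surface import GridSpec

DEFAULT_LINK_DISTANCE = 1.5  # Angstrom
BIOPHYSICAL_CATEGORIES = (
    "asp_glu",
    "acceptor",
    "aromatic",
    "donor",
    "lipophilic",
    "other",
)


@dataclass
class AttributionGrid:
    spec: GridSpec
    scores: np.ndarray  # (P, P, P) on the padded grid, channel-summed
    source: tuple = ()  # (model id, structure id, rotation id)


@dataclass
class SignificanceThreshold:
    sigma: float


@dataclass
class Patch:
    voxels: np.ndarray  # (m, 3) integer indices into the padded grid
    sign: int  # +1 or -1
    scores: np.ndarray  # (m,)
    spec: GridSpec | None = None

    @property
    def size(self) -> int:
        return len(self.voxels)


def integrated_gradients(
    model: Cnn3d,
    x: InputGrid,
    baseline: InputGrid | None = None,
    steps: int = 128,
) -> AttributionGrid:
    """Midpoint-rule integrated gradients against an all-zero baseline.

    The per-voxel scores of multi-channel inputs are summed over channels so
    one spatial attribution map is produced per input grid.
    """
    if steps < 1:
        raise ConfigError("steps must be >= 1")
    xb = x.channels
    b = np.zeros_like(xb) if baseline is None else baseline.channels
    if b.shape != xb.shape:
        raise ConfigError("baseline shape does not match input")
    diff = xb - b
    total = np.zeros_like(xb)
    for k in range(steps):
        alpha = (k + 0.5) / steps
        g = model.input_gradient(b + alpha * diff)
        if not np.all(np.isfinite(g)):
            raise FloatingPointError("non-finite gradients in IG path")
        total += g
    scores = diff * total / steps
    return AttributionGrid(
        spec=x.spec,
        scores=scores.sum(axis=0),
        source=(id(model), x.structure_id, x.rotation_id),
    )


def completeness_gap(
    model: Cnn3d, x: InputGrid, attr: AttributionGrid
) -> float:
    """|sum(scores) - (F(x) - F(0))| relative to |F(x) - F(0)|."""
    fx = model.forward(x.channels, train=False)
    f0 = model.forward(np.zeros_like(x.channels), train=False)
    denom = abs(fx - f0)
    return abs(attr.scores.sum() - (fx - f0)) / max(denom, 1e-300)


def pool_significance(attrs: list[AttributionGrid]) -> SignificanceThreshold:
    """Population std of all nonzero scores pooled over a test set."""
    if not attrs:
        raise DegenerateError("no attribution grids to pool")
    vals = np.concatenate([a.scores[a.scores != 0.0] for a in attrs])
    if vals.size == 0:
        raise DegenerateError("all attribution scores are zero")
    return SignificanceThreshold(sigma=float(np.std(vals)))


def find_patches(
    a: AttributionGrid,
    thr: SignificanceThreshold,
    link_dist: float = DEFAULT_LINK_DISTANCE,
) -> list[Patch]:
    """Connected components of significant voxels, per sign.

    Two voxels belong to the same patch when their center distance is at
    most ``link_dist``.  Patches are sorted by size descending; ties by
    (sign descending, lexicographically smallest voxel index).
    """
    if link_dist < a.spec.spacing:
        raise ConfigError("link distance below the grid spacing")
    patches: list[Patch] = []
    for sign in (+1, -1):
        mask = (a.scores * sign) > thr.sigma
        coords = np.argwhere(mask)
        if len(coords) == 0:
            continue
        pts = coords * a.spec.spacing
        tree = cKDTree(pts)
        pairs = tree.query_pairs(link_dist + 1e-9, output_type="ndarray")
        m = len(coords)
        if len(pairs):
            adj = csr_matrix(
                (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(m, m)
            )
        else:
            adj = csr_matrix((m, m))
        n_comp, labels = connected_components(adj, directed=False)
        for c in range(n_comp):
            sel = labels == c
            patches.append(
                Patch(
                    voxels=coords[sel],
                    sign=sign,
                    scores=a.scores[tuple(coords[sel].T)],
                    spec=a.spec,
                )
            )
    patches.sort(
        key=lambda p: (-p.size, -p.sign, tuple(map(int, p.voxels.min(axis=0))))
    )
    return patches


# ---------------------------------------------------------------------------
# composition analysis


def _atom_category(atom, resname: str) -> str:
    """Priority order: Asp/Glu sidechain > acceptor O > aromatic sidechain >
    donor N / Lys-Arg group > lipophilic C."""
    backbone = {"N", "CA", "C", "O", "OXT"}
    el = atom.element.upper()
    if resname in ("ASP", "GLU") and atom.name not in backbone:
        return "asp_glu"
    if el == "O":
        return "acceptor"
    if resname in AROMATIC_RESIDUES and atom.name not in backbone:
        return "aromatic"
    if el == "N":
        return "donor"
    if resname in CATION_ATOMS and atom.name in CATION_ATOMS[resname]:
        return "donor"
    if el == "C":
        return "lipophilic"
    return "other"


def _voxel_positions(p: Patch, spec: GridSpec) -> np.ndarray:
    """Physical coordinates of patch voxels (padded index -> Angstrom)."""
    return (p.voxels - spec.pad_offset) * spec.spacing - spec.extent


def _nearest_heavy(
    positions: np.ndarray, s: Structure
) -> tuple[np.ndarray, list]:
    heavy_idx = s.heavy_atom_indices()
    heavy = [s.atoms[i] for i in heavy_idx]
    tree = cKDTree(np.array([a.position for a in heavy]))
    _, nn = tree.query(positions)
    return nn, heavy


def classify_patch_points(p: Patch, s: Structure) -> dict[str, float]:
    """Fraction of patch voxels per biophysical category (nearest heavy atom).

    Also reports ``acceptor_mainchain_O`` — the share of acceptor-category
    voxels whose nearest atom is a backbone carbonyl/terminal oxygen.
    """
    if p.size == 0:
        raise DegenerateError("empty patch")
    pos = _voxel_positions(p, _patch_spec(p, s))
    nn, heavy = _nearest_heavy(pos, s)
    counts = dict.fromkeys(BIOPHYSICAL_CATEGORIES, 0)
    mainchain_o = 0
    for i in nn:
        a = heavy[i]
        cat = _atom_category(a, a.residue_name)
        counts[cat] += 1
        if cat == "acceptor" and a.name in ("O", "OXT"):
            mainchain_o += 1
    comp = {k: v / p.size for k, v in counts.items()}
    comp["acceptor_mainchain_O"] = (
        mainchain_o / counts["acceptor"] if counts["acceptor"] else 0.0
    )
    return comp


def _patch_spec(p: Patch, s: Structure) -> GridSpec:
    # patch voxels are padded-grid indices; the GridSpec travels on the patch
    if p.spec is None:
        raise ConfigError("patch has no grid spec attached")
    return p.spec


def segment_composition(
    p: Patch, seg: SegmentMap, s: Structure
) -> dict[str, float]:
    """Fraction of patch voxels per Fv segment of the nearest residue."""
    if p.size == 0:
        raise DegenerateError("empty patch")
    pos = _voxel_positions(p, _patch_spec(p, s))
    nn, heavy = _nearest_heavy(pos, s)
    counts: dict[str, int] = {}
    for i in nn:
        label = seg.label_of(heavy[i].residue_key)
        counts[label] = counts.get(label, 0) + 1
    return {k: v / p.size for k, v in counts.items()}


# ---------------------------------------------------------------------------
# proximal / distal carboxylate analysis


def carboxylate_cation_distances(s: Structure) -> dict[tuple, float]:
    """Min distance from each Asp/Glu carboxylate group to any cation center
    (Lys NZ or an Arg guanidine heavy atom)."""
    cations = [
        a.position
        for a in s.atoms
        if a.residue_name in CATION_ATOMS
        and a.name in CATION_ATOMS[a.residue_name]
    ]
    out: dict[tuple, float] = {}
    for key, atoms in s.residues():
        resname = atoms[0].residue_name
        if resname not in CARBOXYLATE_ATOMS:
            continue
        group = [a.position for a in atoms if a.name in CARBOXYLATE_ATOMS[resname]]
        if not group or not cations:
            out[key] = np.inf if group else np.nan
            continue
        d = min(
            float(np.linalg.norm(g - c)) for g in group for c in cations
        )
        out[key] = d
    return out


def carboxylate_attribution(
    a: AttributionGrid,
    s: Structure,
    proximal_max: float = 3.5,
    distal_min: float = 5.0,
    assoc_dist: float = 4.0,
) -> dict:
    """Mean attribution of grid points associated with proximal vs distal
    carboxylates.

    A carboxylate is proximal when its minimum distance to a cation center is
    <= ``proximal_max``, distal when >= ``distal_min``; in-between residues
    are excluded.  A grid point belongs to a carboxylate when (1) its nearest
    protein heavy atom is part of that carboxyl motif and (2) it lies within
    ``assoc_dist`` of at least one of the three carboxyl atoms.
    """
    dists = carboxylate_cation_distances(s)
    if not dists:
        raise DegenerateError("structure contains no Asp/Glu")
    proximal = {k for k, d in dists.items() if d <= proximal_max}
    distal = {k for k, d in dists.items() if d >= distal_min}

    nz = np.argwhere(a.scores != 0.0)
    pos = (nz - a.spec.pad_offset) * a.spec.spacing - a.spec.extent
    nn, heavy = _nearest_heavy(pos, s)

    carbox_pos = {
        key: np.array(
            [
                at.position
                for at in atoms
                if at.name in CARBOXYLATE_ATOMS[atoms[0].residue_name]
            ]
        )
        for key, atoms in s.residues()
        if atoms[0].residue_name in CARBOXYLATE_ATOMS
    }

    values: dict[str, list[float]] = {"proximal": [], "distal": []}
    for row, i in zip(range(len(nz)), nn):
        at = heavy[i]
        resname = at.residue_name
        if resname not in CARBOXYLATE_ATOMS:
            continue
        if at.name not in CARBOXYLATE_ATOMS[resname]:
            continue
        key = at.residue_key
        group = carbox_pos.get(key)
        if group is None or len(group) == 0:
            continue
        if np.min(np.linalg.norm(group - pos[row], axis=1)) >= assoc_dist:
            continue
        score = float(a.scores[tuple(nz[row])])
        if key in proximal:
            values["proximal"].append(score)
        elif key in distal:
            values["distal"].append(score)
    return {
        "proximal_mean": float(np.mean(values["proximal"]))
        if values["proximal"]
        else None,
        "distal_mean": float(np.mean(values["distal"]))
        if values["distal"]
        else None,
        "n_proximal_points": len(values["proximal"]),
        "n_distal_points": len(values["distal"]),
        "proximal_residues": sorted(proximal),
        "distal_residues": sorted(distal),
    }
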