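"""Comparison baselines: the three-feature sequence regression and a
structure-based clustered-negative-charge score.

The sequence baseline regresses (transformed) viscosity on Fv net charge,
the VL x VH charge-symmetry product, and a hydrophobicity index, with
per-chain charges from Henderson-Hasselbalch fractional ionization at the
formulation pH.  The structure baseline sums, over solvent-exposed heavy
atoms, the negative part of the local charge within a neighborhood radius;
larger scores mean larger or denser negative surface-charge clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import DataError, DegenerateError
from .structure_io import Structure, load_scales
from .surface import GridSpec, OccupancyGrid, compute_ses

_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
_BASIC = {"HIS", "LYS", "ARG"}
_ACIDIC = {"ASP", "GLU"}


@dataclass
class SharmaFeatures:
    q_net: float  # Fv net charge (e)
    csp: float  # VL charge x VH charge (e^2)
    hi: float  # hydrophobicity index (dimensionless)


@dataclass
class SharmaModel:
    coefficients: np.ndarray  # (q_net, csp, hi) slopes
    intercept: float
    transform: str  # log10 | raw
    pH: float | None = None

    def predict_features(self, feats: list[SharmaFeatures]) -> np.ndarray:
        X = np.array([[f.q_net, f.csp, f.hi] for f in feats])
        t = X @ self.coefficients + self.intercept
        return 10.0**t if self.transform == "log10" else t


@dataclass
class ScmScore:
    score: float
    exposure_threshold: float
    radius: float


def _chain_charge(seq: str, pH: float, charged_termini: bool) -> float:
    pka = load_scales()["pka"]
    q = 0.0
    for letter in seq:
        res = _AA3.get(letter.upper())
        if res is None:
            raise DataError(f"invalid amino-acid letter {letter!r}")
        if res in _BASIC:
            q += 1.0 / (1.0 + 10.0 ** (pH - pka[res]))
        elif res in _ACIDIC:
            q -= 1.0 / (1.0 + 10.0 ** (pka[res] - pH))
    if charged_termini and seq:
        q += 1.0 / (1.0 + 10.0 ** (pH - pka["n_term"]))
        q -= 1.0 / (1.0 + 10.0 ** (pka["c_term"] - pH))
    return q


def _hydrophobicity_index(vl: str, vh: str) -> float:
    scale = load_scales()["eisenberg"]
    phob = phil = 0.0
    for letter in vl + vh:
        res = _AA3.get(letter.upper())
        if res is None:
            raise DataError(f"invalid amino-acid letter {letter!r}")
        v = scale[res]
        if v > 0:
            phob += v
        else:
            phil += v
    if phil == 0.0:
        return 0.0  # no hydrophilic residues: index degenerates to zero
    return phob / abs(phil)


def sharma_features(
    vl_seq: str,
    vh_seq: str,
    pH: float = 5.8,
    charged_termini: bool = False,
) -> SharmaFeatures:
    """Net charge, charge-symmetry product, hydrophobicity index."""
    q_vl = _chain_charge(vl_seq, pH, charged_termini)
    q_vh = _chain_charge(vh_seq, pH, charged_termini)
    return SharmaFeatures(
        q_net=q_vl + q_vh,
        csp=q_vl * q_vh,
        hi=_hydrophobicity_index(vl_seq, vh_seq),
    )


def fit_sharma(
    features: list[SharmaFeatures],
    labels_cP: list[float],
    transform: str = "log10",
    pH: float | None = None,
) -> SharmaModel:
    """Ordinary least squares of (transformed) viscosity on the 3 features."""
    if len(features) != len(labels_cP) or len(features) < 4:
        raise DataError("need >= 4 matched feature/label pairs")
    X = np.array([[f.q_net, f.csp, f.hi] for f in features])
    y = np.log10(labels_cP) if transform == "log10" else np.array(labels_cP, float)
    A = np.column_stack([X, np.ones(len(X))])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise DataError("rank-deficient design matrix")
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return SharmaModel(
        coefficients=beta[:3], intercept=float(beta[3]), transform=transform, pH=pH
    )


def atom_exposure(
    s: Structure,
    occ: OccupancyGrid,
    probe_radius: float = 1.4,
    n_points: int = 92,
) -> np.ndarray:
    """Fraction of probe-sphere sample points per heavy atom lying outside
    the solvent-excluded volume (golden-spiral sphere sampling)."""
    spec = occ.spec
    k = np.arange(n_points)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (k + 0.5) / n_points
    r = np.sqrt(1.0 - z * z)
    theta = golden * k
    unit = np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)

    h = spec.spacing
    n = spec.n_points
    heavy = s.heavy_atom_indices()
    coords = s.coords()[heavy]
    radii = s.radii()[heavy]
    out = np.zeros(len(heavy))
    for i, (c, rad) in enumerate(zip(coords, radii)):
        pts = c + (rad + probe_radius) * unit
        idx = np.rint((pts + spec.extent) / h).astype(int)
        inside_grid = np.all((idx >= 0) & (idx < n), axis=1)
        exposed = ~inside_grid.copy()
        ok = idx[inside_grid]
        exposed[inside_grid] = ~occ.interior[ok[:, 0], ok[:, 1], ok[:, 2]]
        out[i] = exposed.mean()
    return out


def scm_score(
    s: Structure,
    exposure_fraction_threshold: float = 0.1,
    radius: float = 10.0,
    probe_radius: float = 1.4,
    spec: GridSpec | None = None,
    occ: OccupancyGrid | None = None,
) -> ScmScore:
    """Clustered-negative-charge score over solvent-exposed heavy atoms.

    score = | sum over exposed heavy atoms of min(0, sum of partial charges
    of all atoms within ``radius``) |.
    """
    if occ is None:
        occ = compute_ses(s, spec or GridSpec(), probe_radius)
    heavy = s.heavy_atom_indices()
    exposure = atom_exposure(s, occ, probe_radius)
    exposed = heavy[exposure > exposure_fraction_threshold]
    if len(exposed) == 0:
        raise DegenerateError("no solvent-exposed heavy atoms")
    coords = s.coords()
    charges = s.charges()
    tree = cKDTree(coords)
    total = 0.0
    for i in exposed:
        nb = tree.query_ball_point(coords[i], radius)
        total += min(0.0, float(charges[nb].sum()))
    return ScmScore(
        score=abs(total),
        exposure_threshold=exposure_fraction_threshold,
        radius=radius,
    )
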