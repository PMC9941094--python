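"""Electrostatic potential and hydrophobicity fields on the cubic grid.

The ESP is obtained from the linearized Poisson-Boltzmann equation

    div(eps * grad(phi)) - eps_out * kappa^2 * phi = -4*pi*C*rho

discretized with a 7-point stencil, harmonic-mean face dielectrics and
trilinear charge spreading, with Dirichlet boundary values from a
Debye-Hueckel sum over the atomic charges.  Potentials are in kT/e at 298 K,
lengths in Angstrom, charges in e (C is the Coulomb prefactor in these
units).  A direct screened-Coulomb sum is available as a fast reference and
supplies the boundary condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import cg
from scipy.spatial.transform import Rotation

from .constants import COULOMB_KT_ANG, inverse_debye_length
from .errors import ConfigError, ConvergenceError, ParameterizationError
from .structure_io import Structure, load_scales
from .surface import GridSpec, OccupancyGrid, ShellMask


@dataclass
class ScalarField:
    spec: GridSpec
    values: np.ndarray  # (n, n, n)
    kind: str  # esp | eisenberg_phobic | eisenberg_philic


@dataclass
class InputGrid:
    """Padded, masked multi-channel voxel grid — the network input."""

    spec: GridSpec
    channels: np.ndarray  # (C, P, P, P) with P = spec.padded_dim
    mask_applied: bool = True
    label_cP: float | None = None
    target: float | None = None
    structure_id: str | None = None
    rotation_id: int | None = None

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]


def _spread_charges_trilinear(s: Structure, spec: GridSpec) -> np.ndarray:
    """Distribute atomic charges onto the 8 surrounding voxels (total conserved)."""
    n = spec.n_points
    h = spec.spacing
    rho = np.zeros((n, n, n))
    q = s.charges()
    if np.any(np.isnan(q)):
        raise ValueError("charges not assigned; run assign_parameters first")
    frac = (s.coords() + spec.extent) / h
    i0 = np.floor(frac).astype(int)
    t = frac - i0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (t[:, 0] if dx else 1 - t[:, 0])
                    * (t[:, 1] if dy else 1 - t[:, 1])
                    * (t[:, 2] if dz else 1 - t[:, 2])
                )
                ix = np.clip(i0[:, 0] + dx, 0, n - 1)
                iy = np.clip(i0[:, 1] + dy, 0, n - 1)
                iz = np.clip(i0[:, 2] + dz, 0, n - 1)
                np.add.at(rho, (ix, iy, iz), q * w)
    return rho


def _debye_sum(
    points: np.ndarray,
    coords: np.ndarray,
    charges: np.ndarray,
    eps_out: float,
    kappa: float,
    r_min: float,
) -> np.ndarray:
    """Screened-Coulomb potential of point charges at ``points`` (kT/e)."""
    phi = np.zeros(len(points))
    for c, q in zip(coords, charges):
        if q == 0.0:
            continue
        r = np.linalg.norm(points - c, axis=1)
        np.maximum(r, r_min, out=r)
        phi += q * np.exp(-kappa * r) / r
    return COULOMB_KT_ANG / eps_out * phi


def solve_esp_debye(
    s: Structure,
    spec: GridSpec,
    eps_out: float = 80.0,
    ionic_strength: float = 0.0,
) -> ScalarField:
    """Direct Debye-Hueckel superposition on every voxel center.

    Singularities are clamped at half the grid spacing.  Exact Coulomb for
    kappa = 0; linear in the charges by construction.
    """
    kappa = inverse_debye_length(ionic_strength, eps_out)
    pts = spec.voxel_centers().reshape(-1, 3)
    phi = _debye_sum(
        pts, s.coords(), s.charges(), eps_out, kappa, 0.5 * spec.spacing
    )
    n = spec.n_points
    return ScalarField(spec=spec, values=phi.reshape(n, n, n), kind="esp")


def solve_esp_fd_pb(
    s: Structure,
    spec: GridSpec,
    eps_in: float = 1.0,
    eps_out: float = 80.0,
    ionic_strength: float = 0.0,
    occupancy: OccupancyGrid | None = None,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> ScalarField:
    """Finite-difference linearized Poisson-Boltzmann potential (kT/e).

    ``occupancy`` defines the dielectric map (interior -> eps_in, exterior ->
    eps_out); without it the dielectric is uniformly eps_out.  The screening
    term applies only in the solvent region.
    """
    if eps_in <= 0 or eps_out <= 0:
        raise ConfigError("dielectric constants must be > 0")
    n = spec.n_points
    h = spec.spacing
    kappa = inverse_debye_length(ionic_strength, eps_out)

    eps = np.full((n, n, n), eps_out)
    solvent = np.ones((n, n, n), dtype=bool)
    if occupancy is not None:
        if occupancy.spec != spec:
            raise ConfigError("occupancy grid spec mismatch")
        eps[occupancy.interior] = eps_in
        solvent = ~occupancy.interior

    rho = _spread_charges_trilinear(s, spec)

    phi = np.zeros((n, n, n))
    boundary = np.zeros((n, n, n), dtype=bool)
    for axis in range(3):
        sl = [slice(None)] * 3
        for edge in (0, n - 1):
            sl[axis] = edge
            boundary[tuple(sl)] = True
    bpts = spec.voxel_centers()[boundary]
    phi[boundary] = _debye_sum(
        bpts, s.coords(), s.charges(), eps_out, kappa, 0.5 * h
    )

    unknown = ~boundary
    m = int(unknown.sum())
    index = -np.ones((n, n, n), dtype=np.int64)
    index[unknown] = np.arange(m)

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    diag = np.zeros(m)
    rhs = 4.0 * np.pi * COULOMB_KT_ANG * rho[unknown] / h**3
    diag += eps_out * kappa**2 * solvent[unknown].astype(float)

    iu, ju, ku = np.nonzero(unknown)
    ids = index[iu, ju, ku]
    eps_c = eps[iu, ju, ku]
    for axis in range(3):
        for step in (-1, 1):
            ni, nj, nk = iu.copy(), ju.copy(), ku.copy()
            (ni, nj, nk)[axis][:] += step
            eps_n = eps[ni, nj, nk]
            a = 2.0 * eps_c * eps_n / (eps_c + eps_n) / h**2
            nb_id = index[ni, nj, nk]
            diag += a
            interior_nb = nb_id >= 0
            rows.append(ids[interior_nb])
            cols.append(nb_id[interior_nb])
            vals.append(-a[interior_nb])
            # Dirichlet neighbors contribute to the right-hand side
            b = ~interior_nb
            np.add.at(rhs, ids[b], a[b] * phi[ni[b], nj[b], nk[b]])

    rows.append(ids)
    cols.append(ids)
    vals.append(diag)
    A = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(m, m),
    )
    M = sparse.diags(1.0 / A.diagonal())
    x, info = cg(A, rhs, rtol=tol, atol=0.0, maxiter=max_iter, M=M)
    if info != 0:
        res = np.linalg.norm(A @ x - rhs) / max(np.linalg.norm(rhs), 1e-300)
        raise ConvergenceError(
            f"PB solver did not converge in {max_iter} iterations "
            f"(relative residual {res:.2e})"
        )
    phi[unknown] = x
    return ScalarField(spec=spec, values=phi, kind="esp")


def _check_alignment(spec: GridSpec, *others) -> None:
    for o in others:
        if o.spec != spec:
            raise ConfigError("grid spec mismatch between field and mask")


def _embed(spec: GridSpec, blocks: list[np.ndarray]) -> np.ndarray:
    p = spec.padded_dim
    o = spec.pad_offset
    n = spec.n_points
    out = np.zeros((len(blocks), p, p, p))
    for c, b in enumerate(blocks):
        out[c, o : o + n, o : o + n, o : o + n] = b
    return out


def build_esp_input(
    phi: ScalarField,
    shell: ShellMask,
    spec: GridSpec,
    label_cP: float | None = None,
) -> InputGrid:
    """Mask the ESP to the surface shell and center it in the padded grid.

    Voxels outside the shell are exactly zero.
    """
    _check_alignment(spec, phi, shell)
    block = np.where(shell.active, phi.values, 0.0)
    return InputGrid(spec=spec, channels=_embed(spec, [block]), label_cP=label_cP)


def eisenberg_density(
    s: Structure,
    spec: GridSpec,
    hydrophobic: bool,
    shell: ShellMask | None = None,
) -> ScalarField:
    """Sum of atom-centered Gaussians for one hydrophobicity class.

    Residues are classified by the sign of their Eisenberg value; each atom
    of a kept residue contributes a unit-height Gaussian whose width is set
    so the density falls to exp(-1) at 3x|scale| Angstrom.
    """
    scale = load_scales()["eisenberg"]
    n = spec.n_points
    values = np.zeros((n, n, n))
    if shell is not None:
        _check_alignment(spec, shell)
        pts = spec.voxel_centers()[shell.active]
    else:
        pts = spec.voxel_centers().reshape(-1, 3)
    acc = np.zeros(len(pts))
    for key, atoms in s.residues():
        resname = atoms[0].residue_name
        if resname not in scale:
            raise ParameterizationError(
                f"residue {resname} {key} has no Eisenberg scale entry"
            )
        v = scale[resname]
        if (v > 0) != hydrophobic:
            continue
        width = 3.0 * abs(v)
        if width == 0.0:
            continue
        for a in atoms:
            d2 = np.sum((pts - a.position) ** 2, axis=1)
            acc += np.exp(-d2 / width**2)
    if shell is not None:
        values[shell.active] = acc
    else:
        values = acc.reshape(n, n, n)
    kind = "eisenberg_phobic" if hydrophobic else "eisenberg_philic"
    return ScalarField(spec=spec, values=values, kind=kind)


def build_eisenberg_input(
    s: Structure,
    shell: ShellMask,
    spec: GridSpec,
    label_cP: float | None = None,
) -> InputGrid:
    """Two-channel (hydrophobic, hydrophilic) masked density grid."""
    _check_alignment(spec, shell)
    blocks = [
        np.where(shell.active, eisenberg_density(s, spec, True, shell).values, 0.0),
        np.where(shell.active, eisenberg_density(s, spec, False, shell).values, 0.0),
    ]
    return InputGrid(spec=spec, channels=_embed(spec, blocks), label_cP=label_cP)


def build_combined_input(
    phi: ScalarField,
    s: Structure,
    shell: ShellMask,
    spec: GridSpec,
    label_cP: float | None = None,
) -> InputGrid:
    """Three channels: masked ESP plus the two Eisenberg densities."""
    esp = build_esp_input(phi, shell, spec)
    eis = build_eisenberg_input(s, shell, spec)
    channels = np.concatenate([esp.channels, eis.channels], axis=0)
    return InputGrid(spec=spec, channels=channels, label_cP=label_cP)


def random_rotation_matrices(n: int, seed: int) -> np.ndarray:
    """(n, 3, 3) uniform random rotation matrices, deterministic given seed."""
    if n < 1:
        raise ConfigError("need at least one rotation")
    rng = np.random.default_rng(seed)
    quat = rng.standard_normal((n, 4))
    quat /= np.linalg.norm(quat, axis=1, keepdims=True)
    return Rotation.from_quat(quat).as_matrix()


def random_rotations(s: Structure, n: int, seed: int) -> list[Structure]:
    """``n`` copies of ``s`` rigidly rotated about the origin (its center of
    mass after canonicalization), with independent uniform rotations."""
    mats = random_rotation_matrices(n, seed)
    out = []
    for k, R in enumerate(mats):
        t = s.copy()
        for a in t.atoms:
            a.position = R @ a.position
        t.provenance.append(f"random_rotation:{seed}:{k}")
        out.append(t)
    return out
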