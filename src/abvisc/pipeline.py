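"""Structure -> network-input featurization, shared by training and inference."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .fields import (
    InputGrid,
    build_combined_input,
    build_eisenberg_input,
    build_esp_input,
    random_rotations,
    solve_esp_debye,
    solve_esp_fd_pb,
)
from .structure_io import Structure
from .surface import GridSpec, compute_ses, compute_shell

REPRESENTATION_CHANNELS = {"esp": 1, "eisenberg": 2, "combined": 3}


@dataclass(frozen=True)
class FeaturizeConfig:
    """Everything needed to turn a parameterized structure into an InputGrid."""

    representation: str = "esp"
    grid: GridSpec = field(default_factory=GridSpec)
    probe_radius: float = 1.4
    shell_thickness: float = 2.0
    solver: str = "fd_pb"  # fd_pb | debye
    eps_in: float = 1.0
    eps_out: float = 80.0
    ionic_strength: float = 0.0
    pb_tol: float = 1e-6
    clip: float | None = None  # optional symmetric ESP clip (kT/e), off by default

    def __post_init__(self):
        if self.representation not in REPRESENTATION_CHANNELS:
            raise ConfigError(f"unknown representation {self.representation!r}")
        if self.solver not in ("fd_pb", "debye"):
            raise ConfigError(f"unknown solver {self.solver!r}")

    @property
    def n_channels(self) -> int:
        return REPRESENTATION_CHANNELS[self.representation]


def featurize_structure(
    s: Structure,
    cfg: FeaturizeConfig,
    label_cP: float | None = None,
) -> InputGrid:
    """SES -> shell -> field(s) -> masked padded grid for one structure pose."""
    occ = compute_ses(s, cfg.grid, cfg.probe_radius)
    shell = compute_shell(occ, cfg.shell_thickness)
    if cfg.representation == "eisenberg":
        return build_eisenberg_input(s, shell, cfg.grid, label_cP=label_cP)
    if cfg.solver == "fd_pb":
        phi = solve_esp_fd_pb(
            s,
            cfg.grid,
            eps_in=cfg.eps_in,
            eps_out=cfg.eps_out,
            ionic_strength=cfg.ionic_strength,
            occupancy=occ,
            tol=cfg.pb_tol,
        )
    else:
        phi = solve_esp_debye(
            s, cfg.grid, eps_out=cfg.eps_out, ionic_strength=cfg.ionic_strength
        )
    if cfg.clip is not None:
        phi.values = np.clip(phi.values, -cfg.clip, cfg.clip)
    if cfg.representation == "esp":
        return build_esp_input(phi, shell, cfg.grid, label_cP=label_cP)
    return build_combined_input(phi, s, shell, cfg.grid, label_cP=label_cP)


def featurize_rotations(
    s: Structure,
    cfg: FeaturizeConfig,
    n_rotations: int,
    seed: int,
    label_cP: float | None = None,
) -> list[InputGrid]:
    """Featurize ``n_rotations`` random rigid rotations of one structure."""
    grids = []
    for k, rs in enumerate(random_rotations(s, n_rotations, seed)):
        g = featurize_structure(rs, cfg, label_cP=label_cP)
        g.rotation_id = k
        grids.append(g)
    return grids
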