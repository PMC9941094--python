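"""scikit-learn-style estimators wrapping the featurization and training
pipeline, so the predictor composes with sklearn model selection and
pipelines.

``EspFeaturizer`` is a stateless transformer (structures -> input grids);
``CnnViscosityRegressor`` trains the cross-validation ensemble of 3D CNNs on
labeled structures and predicts viscosity in cP; ``SharmaViscosityRegressor``
is the three-feature sequence baseline.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .baselines import SharmaFeatures, fit_sharma, sharma_features
from .network import (
    NetworkConfig,
    StructureGrids,
    predict_grids,
    train_cv_ensemble,
)
from .pipeline import FeaturizeConfig, featurize_rotations
from .structure_io import Structure
from .surface import DESK_GRID, GridSpec


class EspFeaturizer(TransformerMixin, BaseEstimator):
    """Transform canonicalized, parameterized structures into masked
    surface-shell voxel grids.

    Stateless: ``fit`` only validates parameters.  ``transform`` returns one
    ``InputGrid`` per structure (the unrotated pose); use
    ``transform_rotations`` for rotation augmentation.
    """

    def __init__(
        self,
        representation: str = "esp",
        extent: float = DESK_GRID.extent,
        spacing: float = DESK_GRID.spacing,
        padded_dim: int = DESK_GRID.padded_dim,
        shell_thickness: float = 2.0,
        probe_radius: float = 1.4,
        solver: str = "fd_pb",
        eps_in: float = 1.0,
        eps_out: float = 80.0,
        ionic_strength: float = 0.0,
    ):
        self.representation = representation
        self.extent = extent
        self.spacing = spacing
        self.padded_dim = padded_dim
        self.shell_thickness = shell_thickness
        self.probe_radius = probe_radius
        self.solver = solver
        self.eps_in = eps_in
        self.eps_out = eps_out
        self.ionic_strength = ionic_strength

    def _config(self) -> FeaturizeConfig:
        return FeaturizeConfig(
            representation=self.representation,
            grid=GridSpec(self.extent, self.spacing, self.padded_dim),
            probe_radius=self.probe_radius,
            shell_thickness=self.shell_thickness,
            solver=self.solver,
            eps_in=self.eps_in,
            eps_out=self.eps_out,
            ionic_strength=self.ionic_strength,
        )

    def fit(self, X=None, y=None):
        self.config_ = self._config()
        return self

    def transform(self, X: list[Structure]):
        cfg = self._config()
        from .pipeline import featurize_structure

        return [featurize_structure(s, cfg) for s in X]

    def transform_rotations(self, X: list[Structure], n_rotations: int, seed: int):
        cfg = self._config()
        return [
            featurize_rotations(s, cfg, n_rotations, seed + i)
            for i, s in enumerate(X)
        ]


class CnnViscosityRegressor(RegressorMixin, BaseEstimator):
    """Cross-validation ensemble of 3D CNNs over rotation-augmented
    surface-shell grids.

    ``fit`` expects a list of parameterized, canonicalized ``Structure``
    objects and viscosities in cP; ``predict`` averages over
    ``n_rotations_infer`` random poses x ``n_folds`` models, in cP.
    Defaults follow the desk-scale profile; the published full-scale
    protocol is ``n_folds=10, n_rotations_train=10, n_rotations_infer=10``
    with the 128-voxel grid and ``NetworkConfig()`` training settings.
    """

    def __init__(
        self,
        representation: str = "esp",
        extent: float = DESK_GRID.extent,
        spacing: float = DESK_GRID.spacing,
        padded_dim: int = DESK_GRID.padded_dim,
        solver: str = "fd_pb",
        n_folds: int = 3,
        n_rotations_train: int = 2,
        n_rotations_infer: int = 2,
        n_blocks: int = 5,
        first_filters: int = 4,
        dropout_rate: float = 0.05,
        learning_rate: float = 1e-3,
        epochs: int = 200,
        selection_window: int = 50,
        target_transform: str = "log10",
        seed: int = 0,
    ):
        self.representation = representation
        self.extent = extent
        self.spacing = spacing
        self.padded_dim = padded_dim
        self.solver = solver
        self.n_folds = n_folds
        self.n_rotations_train = n_rotations_train
        self.n_rotations_infer = n_rotations_infer
        self.n_blocks = n_blocks
        self.first_filters = first_filters
        self.dropout_rate = dropout_rate
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.selection_window = selection_window
        self.target_transform = target_transform
        self.seed = seed

    def _featurizer(self) -> EspFeaturizer:
        return EspFeaturizer(
            representation=self.representation,
            extent=self.extent,
            spacing=self.spacing,
            padded_dim=self.padded_dim,
            solver=self.solver,
        )

    def _network_config(self) -> NetworkConfig:
        return NetworkConfig(
            n_blocks=self.n_blocks,
            first_filters=self.first_filters,
            dropout_rate=self.dropout_rate,
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            selection_window=self.selection_window,
            target_transform=self.target_transform,
        )

    def fit(self, X: list[Structure], y):
        y = np.asarray(y, float)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if np.any(y <= 0):
            raise ValueError("viscosities must be positive (cP)")
        feat = self._featurizer()
        grid_sets = feat.transform_rotations(X, self.n_rotations_train, self.seed)
        dataset = []
        for i, (grids, label) in enumerate(zip(grid_sets, y)):
            for g in grids:
                g.label_cP = float(label)
                g.structure_id = f"s{i:04d}"
            dataset.append(StructureGrids(f"s{i:04d}", grids, float(label)))
        self.ensemble_ = train_cv_ensemble(
            dataset,
            self.n_folds,
            self._network_config(),
            self.seed,
            featurize_config=feat._config(),
        )
        self.n_features_in_ = len(X)
        return self

    def predict(self, X: list[Structure]):
        check_is_fitted(self, "ensemble_")
        feat = self._featurizer()
        out = []
        for i, s in enumerate(X):
            grids = featurize_rotations(
                s, feat._config(), self.n_rotations_infer, self.seed + 50_000 + i
            )
            out.append(predict_grids(self.ensemble_, grids).final_cP)
        return np.array(out)


class SharmaViscosityRegressor(RegressorMixin, BaseEstimator):
    """Three-feature sequence baseline: OLS of (transformed) viscosity on
    Fv net charge, VL x VH charge product, and hydrophobicity index."""

    def __init__(self, pH: float = 5.8, transform: str = "log10"):
        self.pH = pH
        self.transform = transform

    def _features(self, X) -> list[SharmaFeatures]:
        return [sharma_features(vl, vh, pH=self.pH) for vl, vh in X]

    def fit(self, X, y):
        """X: iterable of (VL sequence, VH sequence) pairs; y: cP."""
        self.model_ = fit_sharma(
            self._features(X), list(np.asarray(y, float)), transform=self.transform,
            pH=self.pH,
        )
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict_features(self._features(X))
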