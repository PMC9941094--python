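"""The 3D convolutional regression network and its training protocol.

The network is a stack of [conv(3x3x3, same padding) -> ReLU -> maxpool(2)]
blocks whose filter count doubles per block (4, 8, 16, ...), followed by
flatten, dropout and a single linear output node.  On a 128-voxel
single-channel input with 6 blocks the flattened feature vector has length
1024.  Training minimizes Huber loss with Adam at batch size 1; the
checkpoint with the best validation loss within the final selection window
is kept.  Inference averages predictions over random rotations of the input
structure and over the models of a cross-validation ensemble.

Forward and backward passes are implemented directly on numpy arrays
(sliding-window views + einsum), which keeps the package dependency-free,
fully deterministic under a fixed seed, and also provides the input
gradients needed for integrated-gradients attribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigError, ConvergenceError, DataError
from .fields import InputGrid, random_rotations
from .pipeline import FeaturizeConfig, featurize_structure
from .structure_io import Structure


@dataclass(frozen=True)
class NetworkConfig:
    n_blocks: int = 6
    first_filters: int = 4
    kernel: int = 3
    dropout_rate: float = 0.05
    learning_rate: float = 1e-5
    batch_size: int = 1
    epochs: int = 2000
    selection_window: int = 50
    huber_delta: float = 1.0
    target_transform: str = "log10"  # log10 | raw

    def filters(self) -> list[int]:
        return [self.first_filters * 2**i for i in range(self.n_blocks)]


# NetworkConfig presets: the full-scale profile matches the published
# protocol; the desk profile trades grid size and epochs for runtime and is
# what the tests and synthetic-recovery study use.
FULL_NETWORK = NetworkConfig()
DESK_NETWORK = NetworkConfig(
    n_blocks=5, epochs=200, selection_window=50, learning_rate=1e-3
)


def target_from_cP(label_cP: float, transform: str) -> float:
    if transform == "log10":
        return math.log10(label_cP)
    if transform == "raw":
        return float(label_cP)
    raise ConfigError(f"unknown target transform {transform!r}")


def cP_from_target(t: float, transform: str) -> float:
    if transform == "log10":
        return float(10.0**t)
    if transform == "raw":
        return float(t)
    raise ConfigError(f"unknown target transform {transform!r}")


# ---------------------------------------------------------------------------
# layers


class _Conv3d:
    def __init__(self, in_c: int, out_c: int, k: int, rng: np.random.Generator):
        fan_in = in_c * k**3
        fan_out = out_c * k**3
        limit = math.sqrt(6.0 / (fan_in + fan_out))
        self.w = rng.uniform(-limit, limit, size=(out_c, in_c, k, k, k))
        self.b = np.zeros(out_c)
        self.k = k
        self._xp: np.ndarray | None = None

    def _im2col(self, xp: np.ndarray, d: int) -> np.ndarray:
        # (C*k^3, d^3) patch matrix; the copy makes the conv a single GEMM
        win = sliding_window_view(xp, (self.k,) * 3, axis=(1, 2, 3))
        col = win.transpose(0, 4, 5, 6, 1, 2, 3).reshape(-1, d**3)
        return np.ascontiguousarray(col)

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.k // 2
        d = x.shape[1]
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
        self._col = self._im2col(xp, d)
        self._d = d
        out_c = self.w.shape[0]
        y = self.w.reshape(out_c, -1) @ self._col
        return y.reshape(out_c, d, d, d) + self.b[:, None, None, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        out_c, in_c = self.w.shape[:2]
        d = self._d
        gm = g.reshape(out_c, -1)
        self.gw = (gm @ self._col.T).reshape(self.w.shape)
        self.gb = gm.sum(axis=1)
        dcol = (self.w.reshape(out_c, -1).T @ gm).reshape(
            in_c, self.k, self.k, self.k, d, d, d
        )
        p = self.k // 2
        dxp = np.zeros((in_c, d + 2 * p, d + 2 * p, d + 2 * p))
        for i in range(self.k):
            for j in range(self.k):
                for l in range(self.k):
                    dxp[:, i : i + d, j : j + d, l : l + d] += dcol[:, i, j, l]
        return dxp[:, p : p + d, p : p + d, p : p + d]

    def params(self):
        return [("w", self), ("b", self)]


class _ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.where(self._mask, g, 0.0)


class _MaxPool2:
    def forward(self, x: np.ndarray) -> np.ndarray:
        c, d = x.shape[0], x.shape[1]
        if d % 2:
            raise ConfigError(f"maxpool on odd dimension {d}")
        h = d // 2
        xr = (
            x.reshape(c, h, 2, h, 2, h, 2)
            .transpose(0, 1, 3, 5, 2, 4, 6)
            .reshape(c, h, h, h, 8)
        )
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, g: np.ndarray) -> np.ndarray:
        c, h = g.shape[0], g.shape[1]
        z = np.zeros((c, h, h, h, 8))
        np.put_along_axis(z, self._idx[..., None], g[..., None], axis=-1)
        return (
            z.reshape(c, h, h, h, 2, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3, 6)
            .reshape(self._shape)
        )


class _Dropout:
    def __init__(self, rate: float):
        self.rate = rate

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g if self._mask is None else g * self._mask


class _Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = math.sqrt(6.0 / (n_in + n_out))
        self.w = rng.uniform(-limit, limit, size=(n_out, n_in))
        self.b = np.zeros(n_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return self.w @ x + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.gw = np.outer(g, self._x)
        self.gb = g.copy()
        return self.w.T @ g


# ---------------------------------------------------------------------------
# model


class Cnn3d:
    """Single-sample 3D CNN regressor with analytic backprop."""

    def __init__(self, cfg: NetworkConfig, in_channels: int, in_dim: int, seed: int):
        if cfg.n_blocks > 0 and in_dim % 2**cfg.n_blocks != 0:
            raise ConfigError(
                f"input dim {in_dim} not divisible by 2^{cfg.n_blocks}"
            )
        self.cfg = cfg
        self.in_channels = in_channels
        self.in_dim = in_dim
        rng = np.random.default_rng(seed)
        self.convs: list[_Conv3d] = []
        self.relus: list[_ReLU] = []
        self.pools: list[_MaxPool2] = []
        c = in_channels
        for f in cfg.filters():
            self.convs.append(_Conv3d(c, f, cfg.kernel, rng))
            self.relus.append(_ReLU())
            self.pools.append(_MaxPool2())
            c = f
        spatial = in_dim // 2**cfg.n_blocks
        self.flatten_dim = c * spatial**3
        self.dropout = _Dropout(cfg.dropout_rate)
        self.head = _Linear(self.flatten_dim, 1, rng)

    def forward(
        self,
        x: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> float:
        if x.shape != (self.in_channels, self.in_dim, self.in_dim, self.in_dim):
            raise ConfigError(
                f"input shape {x.shape} does not match model "
                f"({self.in_channels}, {self.in_dim}^3)"
            )
        h = x
        for conv, relu, pool in zip(self.convs, self.relus, self.pools):
            h = pool.forward(relu.forward(conv.forward(h)))
        self._pre_flatten_shape = h.shape
        h = h.reshape(-1)
        h = self.dropout.forward(h, train, rng)
        return float(self.head.forward(h)[0])

    def backward(self, dout: float = 1.0) -> np.ndarray:
        """Backpropagate; stores parameter grads, returns the input gradient."""
        g = self.head.backward(np.array([dout]))
        g = self.dropout.backward(g)
        g = g.reshape(self._pre_flatten_shape)
        for conv, relu, pool in zip(
            reversed(self.convs), reversed(self.relus), reversed(self.pools)
        ):
            g = conv.backward(relu.backward(pool.backward(g)))
        return g

    def input_gradient(self, x: np.ndarray) -> np.ndarray:
        """d(output)/d(input) in inference mode (dropout off)."""
        self.forward(x, train=False)
        return self.backward(1.0)

    # -- parameter access -------------------------------------------------
    def _param_layers(self):
        return list(self.convs) + [self.head]

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for layer in self._param_layers():
            out.append(layer.w.copy())
            out.append(layer.b.copy())
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for layer in self._param_layers():
            layer.w = next(it).copy()
            layer.b = next(it).copy()

    def n_parameters(self) -> int:
        return sum(w.size for w in self.get_weights())


def build_model(cfg: NetworkConfig, in_channels: int, in_dim: int, seed: int = 0) -> Cnn3d:
    """Glorot-initialized, untrained network for the given input geometry."""
    return Cnn3d(cfg, in_channels, in_dim, seed)


# ---------------------------------------------------------------------------
# loss and optimizer


def huber(residual: float, delta: float) -> tuple[float, float]:
    """Huber loss value and derivative w.r.t. the residual."""
    a = abs(residual)
    if a <= delta:
        return 0.5 * residual**2, residual
    return delta * (a - 0.5 * delta), math.copysign(delta, residual)


class _Adam:
    def __init__(self, shapes, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        c1 = 1.0 - self.b1**self.t
        c2 = 1.0 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


# ---------------------------------------------------------------------------
# training protocol


@dataclass
class TrainedModel:
    model: Cnn3d
    config: NetworkConfig
    fold_id: int
    training_log: list[tuple[float, float]]  # (train_loss, val_loss) per epoch
    selected_epoch: int  # 1-based


@dataclass
class StructureGrids:
    """All featurized poses of one labeled structure."""

    structure_id: str
    grids: list[InputGrid]
    label_cP: float


@dataclass
class Ensemble:
    models: list[TrainedModel]
    featurize_config: FeaturizeConfig
    target_transform: str
    splits: list[dict] = field(default_factory=list)


@dataclass
class PredictionRecord:
    structure_id: str
    predictions_cP: list[float]
    final_cP: float

    @property
    def n_predictions(self) -> int:
        return len(self.predictions_cP)


def _grid_xy(g: InputGrid, transform: str) -> tuple[np.ndarray, float]:
    if g.label_cP is None:
        raise DataError(f"grid for {g.structure_id} has no viscosity label")
    return g.channels, target_from_cP(g.label_cP, transform)


def train_fold(
    train: list[InputGrid],
    val: list[InputGrid],
    cfg: NetworkConfig,
    seed: int,
    fold_id: int = 0,
) -> TrainedModel:
    """Train one network; keep the best-validation checkpoint from the final
    selection window (ties broken toward the later epoch)."""
    if not train or not val:
        raise DataError("training and validation sets must be nonempty")
    transform = cfg.target_transform
    data = [_grid_xy(g, transform) for g in train]
    vdata = [_grid_xy(g, transform) for g in val]
    in_c, in_d = data[0][0].shape[0], data[0][0].shape[1]
    model = Cnn3d(cfg, in_c, in_d, seed)
    rng = np.random.default_rng(seed + 1)
    opt = _Adam([w.shape for w in model.get_weights()], cfg.learning_rate)
    log: list[tuple[float, float]] = []
    best: tuple[float, int, list[np.ndarray]] | None = None
    window_start = max(1, cfg.epochs - cfg.selection_window + 1)
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(len(data))
        tloss = 0.0
        for i in order:
            x, y = data[i]
            pred = model.forward(x, train=True, rng=rng)
            loss, dres = huber(pred - y, cfg.huber_delta)
            if not math.isfinite(loss):
                raise ConvergenceError(f"training diverged at epoch {epoch}")
            tloss += loss
            model.backward(dres)
            layers = model._param_layers()
            params = [a for l in layers for a in (l.w, l.b)]
            grads = [a for l in layers for a in (l.gw, l.gb)]
            opt.step(params, grads)
        tloss /= len(data)
        vloss = 0.0
        for x, y in vdata:
            pred = model.forward(x, train=False)
            vloss += huber(pred - y, cfg.huber_delta)[0]
        vloss /= len(vdata)
        log.append((tloss, vloss))
        if epoch >= window_start and (best is None or vloss <= best[0]):
            best = (vloss, epoch, model.get_weights())
    assert best is not None
    model.set_weights(best[2])
    return TrainedModel(
        model=model,
        config=cfg,
        fold_id=fold_id,
        training_log=log,
        selected_epoch=best[1],
    )


def cv_splits(ids: list[str], k: int, seed: int) -> list[tuple[list[str], list[str]]]:
    """K-fold split by structure id: list of (train_ids, val_ids)."""
    if k > len(ids):
        raise DataError(f"k={k} folds but only {len(ids)} structures")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    folds = [order[i::k] for i in range(k)]
    return [
        ([sid for j, f in enumerate(folds) if j != i for sid in f], folds[i])
        for i in range(k)
    ]


def train_cv_ensemble(
    dataset: list[StructureGrids],
    k: int,
    cfg: NetworkConfig,
    seed: int,
    featurize_config: FeaturizeConfig | None = None,
) -> Ensemble:
    """K models, each trained with one structure-level fold held out.

    All rotations of a structure stay on the same side of every split.
    """
    ids = [d.structure_id for d in dataset]
    if len(set(ids)) != len(ids):
        raise DataError("duplicate structure ids in dataset")
    by_id = {d.structure_id: d for d in dataset}
    splits = cv_splits(ids, k, seed)
    models = []
    meta = []
    for fold_id, (train_ids, val_ids) in enumerate(splits):
        tr = [g for sid in train_ids for g in by_id[sid].grids]
        va = [g for sid in val_ids for g in by_id[sid].grids]
        models.append(train_fold(tr, va, cfg, seed + 100 + fold_id, fold_id))
        meta.append({"fold": fold_id, "train": train_ids, "val": val_ids})
    return Ensemble(
        models=models,
        featurize_config=featurize_config
        or FeaturizeConfig(),
        target_transform=cfg.target_transform,
        splits=meta,
    )


def predict_grids(
    ens: Ensemble, grids: list[InputGrid], structure_id: str = ""
) -> PredictionRecord:
    """Run every ensemble model on every featurized pose and average in cP."""
    preds = []
    for tm in ens.models:
        for g in grids:
            if g.n_channels != tm.model.in_channels:
                raise ConfigError(
                    "representation mismatch between ensemble and input grids"
                )
            t = tm.model.forward(g.channels, train=False)
            preds.append(cP_from_target(t, ens.target_transform))
    return PredictionRecord(
        structure_id=structure_id,
        predictions_cP=preds,
        final_cP=float(np.mean(preds)),
    )


def predict(
    ens: Ensemble,
    s: Structure,
    n_rotations: int = 10,
    seed: int = 0,
    structure_id: str = "",
) -> PredictionRecord:
    """Featurize ``n_rotations`` random poses and average over poses x models
    (10 x 10 = 100 predictions at the published protocol)."""
    grids = []
    for k, rs in enumerate(random_rotations(s, n_rotations, seed)):
        g = featurize_structure(rs, ens.featurize_config)
        g.rotation_id = k
        grids.append(g)
    return predict_grids(ens, grids, structure_id=structure_id)


# ---------------------------------------------------------------------------
# leave-one-out protocol


def loocv_splits(
    ids_a: list[str], ids_b: list[str]
) -> list[tuple[str, list[str]]]:
    """For each id in set A: (held-out id, training ids = A\\{id} U B)."""
    overlap = set(ids_a) & set(ids_b)
    if overlap:
        raise DataError(f"sets overlap: {sorted(overlap)}")
    return [(a, [x for x in ids_a if x != a] + list(ids_b)) for a in ids_a]


def loocv_protocol(
    set_a: list[StructureGrids],
    set_b: list[StructureGrids],
    cfg: NetworkConfig,
    seed: int,
    k: int = 10,
    featurize_config: FeaturizeConfig | None = None,
) -> list[PredictionRecord]:
    """Leave-one-out over set A with set B always in training.

    Each left-out structure is predicted by a k-fold CV ensemble trained on
    the remaining structures of A plus all of B (58 at the published sizes
    21 + 38).
    """
    by_id = {d.structure_id: d for d in set_a + set_b}
    if len(by_id) != len(set_a) + len(set_b):
        raise DataError("sets overlap or contain duplicate ids")
    records = []
    for i, (test_id, train_ids) in enumerate(
        loocv_splits(
            [d.structure_id for d in set_a], [d.structure_id for d in set_b]
        )
    ):
        dataset = [by_id[sid] for sid in train_ids]
        ens = train_cv_ensemble(
            dataset, k, cfg, seed + 1000 * i, featurize_config=featurize_config
        )
        rec = predict_grids(ens, by_id[test_id].grids, structure_id=test_id)
        records.append(rec)
    return records
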