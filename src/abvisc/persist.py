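"""Saving and loading of ensembles, input grids and run artifacts."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .fields import InputGrid
from .network import Cnn3d, Ensemble, NetworkConfig, TrainedModel
from .pipeline import FeaturizeConfig
from .surface import GridSpec


def save_input_grid(g: InputGrid, path: str | Path) -> None:
    np.savez_compressed(
        path,
        channels=g.channels.astype(np.float32),
        extent=g.spec.extent,
        spacing=g.spec.spacing,
        padded_dim=g.spec.padded_dim,
        label_cP=np.nan if g.label_cP is None else g.label_cP,
        structure_id=str(g.structure_id),
        rotation_id=-1 if g.rotation_id is None else g.rotation_id,
    )


def load_input_grid(path: str | Path) -> InputGrid:
    z = np.load(path, allow_pickle=False)
    label = float(z["label_cP"])
    return InputGrid(
        spec=GridSpec(float(z["extent"]), float(z["spacing"]), int(z["padded_dim"])),
        channels=z["channels"].astype(float),
        label_cP=None if np.isnan(label) else label,
        structure_id=str(z["structure_id"]),
        rotation_id=None if int(z["rotation_id"]) < 0 else int(z["rotation_id"]),
    )


def _featurize_config_dict(cfg: FeaturizeConfig) -> dict:
    d = asdict(cfg)
    d["grid"] = asdict(cfg.grid)
    return d


def _featurize_config_from(d: dict) -> FeaturizeConfig:
    d = dict(d)
    d["grid"] = GridSpec(**d["grid"])
    return FeaturizeConfig(**d)


def save_ensemble(ens: Ensemble, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "target_transform": ens.target_transform,
        "featurize": _featurize_config_dict(ens.featurize_config),
        "splits": ens.splits,
        "models": [],
    }
    for tm in ens.models:
        name = f"model_{tm.fold_id:02d}.npz"
        arrays = {f"p{i}": w for i, w in enumerate(tm.model.get_weights())}
        np.savez_compressed(out / name, **arrays)
        meta["models"].append(
            {
                "file": name,
                "fold_id": tm.fold_id,
                "selected_epoch": tm.selected_epoch,
                "config": asdict(tm.config),
                "in_channels": tm.model.in_channels,
                "in_dim": tm.model.in_dim,
                "training_log": tm.training_log,
            }
        )
    (out / "ensemble.json").write_text(json.dumps(meta, indent=2))


def load_ensemble(out_dir: str | Path) -> Ensemble:
    out = Path(out_dir)
    meta = json.loads((out / "ensemble.json").read_text())
    models = []
    for m in meta["models"]:
        cfg = NetworkConfig(**m["config"])
        model = Cnn3d(cfg, m["in_channels"], m["in_dim"], seed=0)
        z = np.load(out / m["file"])
        model.set_weights([z[f"p{i}"] for i in range(len(z.files))])
        models.append(
            TrainedModel(
                model=model,
                config=cfg,
                fold_id=m["fold_id"],
                training_log=[tuple(t) for t in m["training_log"]],
                selected_epoch=m["selected_epoch"],
            )
        )
    return Ensemble(
        models=models,
        featurize_config=_featurize_config_from(meta["featurize"]),
        target_transform=meta["target_transform"],
        splits=meta["splits"],
    )
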