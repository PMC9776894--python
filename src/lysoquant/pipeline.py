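"""End-to-end pipeline orchestration with config validation and provenance.

A run config (YAML/dict) describes a simulated puncta experiment: a set of
conditions, each imaged in several independent experiments, scored for
puncta positivity and compared to a reference condition with Welch t-tests
on per-experiment positivity values. Outputs are per-stage CSVs and a
machine-readable JSON summary embedding the config hash, package version and
seed, so identical config + seed reproduces a byte-identical summary.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .puncta import classify_positive, detect_puncta
from .segmentation import remove_border_objects, segment_cells, segment_nuclei
from .simulate import ImageSimParams, generate_cell_image
from .stats import welch_t

__all__ = ["validate_config", "config_hash", "run_pipeline", "ConfigError"]


class ConfigError(ValueError):
    """Raised when a run config violates the schema."""


_IMAGE_KEYS = {f.name for f in ImageSimParams.__dataclass_fields__.values()}

_SCHEMA = {
    "seed": int,
    "channel": str,
    "min_puncta": int,
    "tophat_radius": (int, float),
    "intensity_thresh": (int, float),
    "min_size": (int, float),
    "max_size": (int, float),
    "n_experiments": int,
    "reference": str,
    "conditions": list,
}
_CONDITION_SCHEMA = {"name": str, "n_images": int, "image": dict}
_DEFAULTS = {
    "seed": 0,
    "channel": "galectin3",
    "min_puncta": 3,
    "tophat_radius": 5,
    "intensity_thresh": 15.0,
    "min_size": 3,
    "max_size": 400,
    "n_experiments": 3,
}


def validate_config(config: dict) -> dict:
    """Validate a run config against the schema; returns it with defaults.

    Unknown keys are reported by name before any stage runs.
    """
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    for key in config:
        if key not in _SCHEMA:
            raise ConfigError(f"unknown config key {key!r}")
    out = {**_DEFAULTS, **config}
    for key, typ in _SCHEMA.items():
        if key in out and key != "conditions" and not isinstance(out[key], typ):
            raise ConfigError(f"config key {key!r} must be {typ}")
    if "conditions" not in out or not out["conditions"]:
        raise ConfigError("config requires a non-empty 'conditions' list")
    names = []
    for cond in out["conditions"]:
        for key in cond:
            if key not in _CONDITION_SCHEMA:
                raise ConfigError(f"unknown condition key {key!r}")
        if "name" not in cond:
            raise ConfigError("every condition needs a 'name'")
        for key in cond.get("image", {}):
            if key not in _IMAGE_KEYS:
                raise ConfigError(f"unknown image parameter {key!r}")
        names.append(cond["name"])
    if len(set(names)) != len(names):
        raise ConfigError("condition names must be unique")
    out.setdefault("reference", names[0])
    if out["reference"] not in names:
        raise ConfigError(f"reference {out['reference']!r} is not a condition")
    return out


def config_hash(config: dict) -> str:
    """Stable SHA-256 of the canonical JSON form of a config."""
    blob = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()


def run_pipeline(config: dict, out_dir) -> dict:
    """Simulate -> segment -> detect -> score -> test, then write a bundle.

    For every condition and experiment, images are simulated with seeds
    derived from the master seed, cells segmented (border objects removed),
    puncta detected on the configured channel and positivity classified.
    Welch t-tests compare each condition's per-experiment percent-positive
    values to the reference condition. Returns the summary dict (also
    written to ``summary.json`` along with per-cell and per-experiment CSVs).
    """
    config = validate_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)

    channel = config["channel"]
    records = []
    root = np.random.SeedSequence(config["seed"])
    for ci, cond in enumerate(config["conditions"]):
        image_cfg = dict(cond.get("image", {}))
        image_cfg.setdefault("puncta_channels", {channel: 80.0})
        for e in range(config["n_experiments"]):
            for i in range(cond.get("n_images", 1)):
                seed = int(root.spawn(1)[0].generate_state(1)[0] % (2**31))
                params = ImageSimParams(**{**image_cfg, "seed": seed})
                image, _truth = generate_cell_image(params)
                nuclei = segment_nuclei(image)
                cells = remove_border_objects(segment_cells(image, nuclei))
                table = detect_puncta(
                    image,
                    channel,
                    cells,
                    tophat_radius=config["tophat_radius"],
                    intensity_thresh=config["intensity_thresh"],
                    min_size=config["min_size"],
                    max_size=config["max_size"],
                )
                if cells.n_objects == 0:
                    continue
                res = classify_positive(table, cells, min_puncta=config["min_puncta"])
                records.append(
                    {
                        "condition": cond["name"],
                        "experiment": f"exp{e + 1}",
                        "image": i,
                        "total_cells": res.total_cells,
                        "positive_cells": res.positive_cells,
                        "percent_positive": res.percent_positive,
                    }
                )
    per_image = pd.DataFrame(records)
    per_image.to_csv(out_dir / "per_image.csv", index=False)

    grouped = per_image.groupby(["condition", "experiment"], sort=True)
    per_exp = (
        100.0
        * grouped["positive_cells"].sum()
        / grouped["total_cells"].sum()
    ).rename("percent_positive").reset_index()
    per_exp.to_csv(out_dir / "per_experiment.csv", index=False)

    ref = config["reference"]
    ref_vals = per_exp.loc[per_exp["condition"] == ref, "percent_positive"].to_numpy()
    summary: dict = {
        "provenance": {
            "config_hash": chash,
            "package_version": __version__,
            "seed": config["seed"],
        },
        "conditions": {},
    }
    for cond in config["conditions"]:
        name = cond["name"]
        vals = per_exp.loc[per_exp["condition"] == name, "percent_positive"].to_numpy()
        entry = {
            "percent_positive_mean": float(vals.mean()),
            "percent_positive_sd": float(vals.std(ddof=1)) if vals.size > 1 else None,
            "n_experiments": int(vals.size),
        }
        if name != ref and vals.size >= 2 and ref_vals.size >= 2:
            t = welch_t(vals, ref_vals)
            entry["welch_p_vs_reference"] = float(t.pvalue)
            entry["welch_t_vs_reference"] = float(t.statistic)
        summary["conditions"][name] = entry

    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
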