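"""Configuration loading: packaged defaults and user YAML overrides."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .grn_models import CisTransParams, InductionParams, InhibitionParams
from .imaging import SegmentationParams

__all__ = ["default_config", "load_config", "model_params_from_config", "segmentation_params_from_config"]

_PARAM_CLASSES = {
    "induction": InductionParams,
    "inhibition": InhibitionParams,
    "cistrans": CisTransParams,
}


def default_config() -> dict:
    """The packaged default parameter set (deep copy, safe to mutate)."""
    with resources.files("notopattern.data").joinpath("default_params.yaml").open() as fh:
        return yaml.safe_load(fh)


def load_config(path: str | Path | None = None) -> dict:
    """Packaged defaults, shallow-merged per section with a user YAML file."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        for section, values in user.items():
            if isinstance(values, dict) and isinstance(cfg.get(section), dict):
                cfg[section].update(values)
            else:
                cfg[section] = values
    return cfg


def model_params_from_config(model_name: str, cfg: dict):
    """Instantiate the parameter dataclass for a model from a config dict."""
    try:
        cls = _PARAM_CLASSES[model_name]
    except KeyError:
        raise KeyError(f"unknown model {model_name!r}") from None
    section = cfg.get(model_name, {})
    valid = {f for f in cls.__dataclass_fields__}
    unknown = set(section) - valid
    if unknown:
        raise ValueError(f"unknown parameter(s) for {model_name}: {sorted(unknown)}")
    return cls(**section)


def segmentation_params_from_config(cfg: dict) -> SegmentationParams:
    section = dict(cfg.get("segmentation", {}))
    valid = set(SegmentationParams.__dataclass_fields__)
    unknown = set(section) - valid
    if unknown:
        raise ValueError(f"unknown segmentation parameter(s): {sorted(unknown)}")
    for key in ("local_kernel_diameter", "dilate_fill", "erode_fill", "min_area",
                "boundary_dilate", "neighborhood_dilate"):
        if key in section:
            section[key] = int(section[key])
    return SegmentationParams(**section)
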