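"""Flat key-value configuration for protocols, constants and priors.

Keys use explicit unit suffixes (``te_s``, ``taus_s``, ``b0_T`` ...); any
subset may appear in a YAML file, the rest fall back to the package
defaults.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .asl_quant import AslProtocol
from .forward_model import AseProtocol, TissueConstants
from .qbold_fit import PriorSpec

__all__ = [
    "load_config",
    "ase_protocol_from_config",
    "tissue_constants_from_config",
    "priors_from_config",
    "asl_protocol_from_config",
]


def load_config(path) -> dict:
    """Read a YAML config file into a flat dict (empty file -> {})."""
    with open(Path(path)) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping of keys to values")
    return data


def ase_protocol_from_config(cfg: dict) -> AseProtocol:
    kwargs = {}
    if "te_s" in cfg:
        kwargs["te"] = float(cfg["te_s"])
    if "tr_s" in cfg:
        kwargs["tr"] = float(cfg["tr_s"])
    if "taus_s" in cfg:
        kwargs["taus"] = tuple(float(t) for t in cfg["taus_s"])
    if "b0_T" in cfg:
        kwargs["b0"] = float(cfg["b0_T"])
    return AseProtocol(**kwargs)


def tissue_constants_from_config(cfg: dict) -> TissueConstants:
    kwargs = {}
    for key, name in (("gamma", "gamma"), ("dchi0", "dchi0"),
                      ("r2t_s", "r2t"), ("hct", "hct")):
        if key in cfg:
            kwargs[name] = float(cfg[key])
    return TissueConstants(**kwargs)


def priors_from_config(cfg: dict) -> PriorSpec:
    kwargs = {}
    for key, name in (("mu0_r2p_s", "mu0_r2p"), ("mu0_dbv", "mu0_dbv"),
                      ("sigma0_r2p_s", "sigma0_r2p"), ("sigma0_dbv", "sigma0_dbv")):
        if key in cfg:
            kwargs[name] = float(cfg[key])
    return PriorSpec(**kwargs)


def asl_protocol_from_config(cfg: dict) -> AslProtocol:
    kwargs = {}
    for key, name in (("plds_s", "plds"), ("label_duration_s", "label_duration"),
                      ("t1b_s", "t1b"), ("t1t_s", "t1t"), ("lambda_ml_g", "lam"),
                      ("alpha", "alpha")):
        if key in cfg:
            val = cfg[key]
            kwargs[name] = tuple(float(v) for v in val) if name == "plds" else float(val)
    return AslProtocol(**kwargs)
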