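"""Named simulation presets: load, calibrate and build scenario objects.

Presets live in ``presets.yaml`` alongside this module.  Each names a design
(``independent`` or ``correlated``), its dimensions, and the calibration
targets — a Monte-Carlo mean first-stage F for the main effects and, for
correlated designs, a target mean pairwise genotype r².  Building a preset
performs the calibration, so scenario construction is deterministic given
the calibration seed.
"""

from __future__ import annotations

import dataclasses
from importlib import resources

import yaml

from .simulate import (
    CorrelatedScenario,
    IndependentScenario,
    calibrate_strength,
    calibrate_theta,
)

__all__ = ["list_presets", "load_presets", "build_preset", "scenario_from_config"]


def load_presets() -> dict:
    """Raw preset definitions (including the shared defaults block)."""
    text = resources.files("mrsummary").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def list_presets() -> list[str]:
    return sorted(k for k in load_presets() if k != "defaults")


def scenario_from_config(cfg: dict, calibration_reps: int = 200,
                         calibration_seed: int = 0):
    """Build a scenario from a key/value mapping, calibrating if requested.

    Recognized keys: ``design`` (independent | correlated), ``n``, ``k``,
    ``maf``, ``beta``, ``conf_x``, ``conf_y``, ``sd_ex``, ``sd_ey``,
    ``sd_u``, ``alpha_main``, ``alpha_int``, and either explicit effect
    sizes or ``calibrate_main_f``; correlated designs take ``theta`` or
    ``target_r2``.
    """
    cfg = dict(cfg)
    design = cfg.pop("design", "independent")
    target_f = cfg.pop("calibrate_main_f", None)
    target_r2 = cfg.pop("target_r2", None)
    k = int(cfg.get("k", 3))
    common = {key: cfg[key] for key in
              ("n", "k", "beta", "conf_x", "conf_y", "sd_ex", "sd_ey", "sd_u")
              if key in cfg}
    alpha_main = tuple(cfg.get("alpha_main", (0.2,) * k))

    if design == "independent":
        alpha_int = tuple(cfg.get("alpha_int", (0.0, 0.0, 0.0)))
        if "maf" in cfg:
            common["maf"] = cfg["maf"]
        template = IndependentScenario(alpha_main=alpha_main,
                                       alpha_int=(0.0, 0.0, 0.0), **common)
        if target_f is not None:
            template = calibrate_strength(template, float(target_f),
                                          reps=calibration_reps,
                                          seed=calibration_seed)
        return dataclasses.replace(template, alpha_int=alpha_int)
    if design == "correlated":
        theta = float(cfg.get("theta", 0.0))
        if target_r2 is not None:
            theta = calibrate_theta(float(target_r2))
        template = CorrelatedScenario(theta=0.0, alpha_main=alpha_main, **common)
        if target_f is not None:
            # strength is calibrated on the LD-free analogue, then LD applied
            template = calibrate_strength(template, float(target_f),
                                          reps=calibration_reps,
                                          seed=calibration_seed)
        return dataclasses.replace(template, theta=theta)
    raise ValueError(f"unknown design {design!r}")


def build_preset(name: str, calibration_reps: int = 200,
                 calibration_seed: int = 0):
    """Build the named preset scenario (with effect-size calibration)."""
    presets = load_presets()
    if name not in presets or name == "defaults":
        raise ValueError(
            f"unknown preset {name!r}; available: {', '.join(list_presets())}"
        )
    cfg = dict(presets.get("defaults", {}))
    cfg.update(presets[name])
    if cfg.get("design") == "correlated":
        cfg.pop("maf", None)  # allele frequency is fixed at 0.5 by the design
    return scenario_from_config(cfg, calibration_reps=calibration_reps,
                                calibration_seed=calibration_seed)
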