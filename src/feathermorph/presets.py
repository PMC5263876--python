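"""Versioned parameter presets.

All numeric defaults live in ``config/defaults.yaml``; each named preset
file overrides only what distinguishes it (chiefly the CRABP1/CYP26B1
gradient amplitudes and slopes).  Loading returns fully validated
:class:`~feathermorph.mrf.MRFParameters` / :class:`~feathermorph.pb.PBParameters`
plus the zone/geometry/run configuration.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from importlib import resources

import yaml

from .gradients import GradientSpec
from .mrf import MRFParameters
from .pb import PBParameters

PRESET_NAMES = (
    "symmetric_no_RA",
    "high_RA",
    "low_RA",
    "gradient_steep",
    "gradient_intermediate",
    "gradient_shallow",
    "grem1_overexpression",
    "dnrar_block",
)


@dataclass(frozen=True)
class Preset:
    name: str
    description: str
    mrf: MRFParameters
    pb: PBParameters
    zones: dict
    geometry: dict
    run: dict


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def _load_yaml(name: str) -> dict:
    path = resources.files("feathermorph").joinpath("config", f"{name}.yaml")
    with path.open("r") as fh:
        return yaml.safe_load(fh) or {}


def _gradient(cfg: dict) -> GradientSpec:
    return GradientSpec(
        a=float(cfg["a"]), v=float(cfg.get("v", 0.0)),
        axis=cfg.get("axis", "lateral_medial"),
        form=cfg.get("form", "exponential"),
    )


def _mrf_from_config(cfg: dict) -> MRFParameters:
    m = cfg["mrf"]
    h = cfg["hill"]
    g = cfg["gradients"]
    b = m["binding"]
    kn = {}
    links = {}
    for link, spec in h.items():
        idx = int(spec["index"])
        links[link] = idx
        kn[f"k{idx}"] = float(spec["k"])
        kn[f"n{idx}"] = float(spec["n"])
    return MRFParameters(
        V_RAo=float(m["RA_o"]["V"]), B_RAo=float(m["RA_o"]["B"]),
        D_RAo=float(m["RA_o"]["D"]), r_RAo=float(m["RA_o"]["r"]),
        B_RAi=float(m["RA_i"]["B"]),
        r_RAi1=float(m["RA_i"]["r_free"]), r_RAi2=float(m["RA_i"]["r_bound"]),
        B_R=float(m["R"]["B"]),
        r_R1=float(m["R"]["r_free"]), r_R2=float(m["R"]["r_bound"]),
        V_BP=float(m["BP"]["V"]), B_BP=float(m["BP"]["B"]),
        r_BP1=float(m["BP"]["r_free"]), r_BP2=float(m["BP"]["r_bound"]),
        V_WNT=float(m["WNT"]["V"]), B_WNT=float(m["WNT"]["B"]),
        D_WNT=float(m["WNT"]["D"]), r_WNT=float(m["WNT"]["r"]),
        V_GDF=float(m["GDF"]["V"]), B_GDF=float(m["GDF"]["B"]),
        D_GDF=float(m["GDF"]["D"]), r_GDF=float(m["GDF"]["r"]),
        V_GREM=float(m["GREM"]["V"]), B_GREM=float(m["GREM"]["B"]),
        D_GREM=float(m["GREM"]["D"]), r_GREM=float(m["GREM"]["r"]),
        k_on=float(b["k_on"]), k_off=float(b["k_off"]),
        m_on=float(b["m_on"]), m_off=float(b["m_off"]),
        j_alpha=float(b["j_alpha"]), j_beta=float(b["j_beta"]),
        k_p=float(b["k_p"]), beta_loss=float(b["beta_loss"]),
        r_cyp=float(m["cyp"]["r_cyp"]), cyp_target=m["cyp"]["target"],
        rar_grem_floor=float(m["grem_response"]["floor"]),
        hill_links=links, **kn,
        grad_CYP=_gradient(g["CYP"]), grad_BP=_gradient(g["BP"]),
        grad_WNT=_gradient(g["WNT"]), grad_RAo=_gradient(g["RAo"]),
    )


def _pb_from_config(cfg: dict) -> PBParameters:
    return PBParameters(**{k: (v if k == "s_c_placement" else float(v))
                           for k, v in cfg["pb"].items()})


def load_defaults() -> dict:
    return _load_yaml("defaults")


def load_preset(name: str) -> Preset:
    """Merge a named preset over the defaults and build parameter objects."""
    if name not in PRESET_NAMES:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
        )
    cfg = _deep_merge(load_defaults(), _load_yaml(name))
    return Preset(
        name=name,
        description=cfg.get("description", name),
        mrf=_mrf_from_config(cfg),
        pb=_pb_from_config(cfg),
        zones=cfg["zones"],
        geometry=cfg["geometry"],
        run=cfg["run"],
    )


def load_pb_variant(name: str) -> PBParameters:
    """Named PB parameter set from the ``pb_variants`` section."""
    cfg = load_defaults()
    variants = cfg.get("pb_variants", {})
    if name not in variants:
        raise KeyError(f"unknown PB variant {name!r}")
    merged = {**cfg["pb"], **variants[name]}
    return _pb_from_config({"pb": merged})


def catalog() -> dict[str, Preset]:
    return {name: load_preset(name) for name in PRESET_NAMES}
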