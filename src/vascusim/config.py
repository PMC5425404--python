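"""Simulation configuration: typed parameter blocks, YAML I/O, defaults.

All physical parameters live in internal units (um, s, Pa, nM).  YAML
config files may give any of them as unit-suffixed strings ("30 min",
"1.33 kPa", "3.0 nM"), which are converted at load time.  The resolved
configuration (every default filled in, plain numbers) is echoed alongside
simulation outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, is_dataclass
from pathlib import Path

import yaml

from .cells import NORMAL, TUMOR, CellTypeParameters
from .hemodynamics import AdaptationParameters, RheologyParameters
from .units import parse_quantity

__all__ = ["SimulationConfig", "TransportSpeciesParameters",
           "default_tumor_config", "default_cornea_config",
           "load_config", "save_config"]

# dimension hints used when parsing unit-suffixed strings
_DIMENSIONS = {
    "dt_global": "time", "dt_ode": "time", "end_time": "time",
    "t_min": "time", "t_death": "time",
    "grid_spacing": "length", "tumor_seed_diameter": "length",
    "shell_outer_radius": "length", "shell_thickness": "length",
    "pellet_side": "length", "pellet_depth": "length",
    "attraction_radius": "length", "anastomosis_radius": "length",
    "sprout_exclusion_distance": "length", "sprout_radius": "length",
    "r_min": "length", "r_max": "length",
    "inlet_pressure": "pressure", "outlet_pressure": "pressure",
    "tau_ref": "pressure",
    "c_phi": "concentration", "c_hypoxia": "concentration",
    "c_death": "concentration", "c_50": "concentration",
    "vascular_concentration": "concentration",
    "pellet_concentration": "concentration",
    "plasma_viscosity": "viscosity",
    "diffusivity": "diffusivity",
    "tip_speed": "speed",
    "k_vegf_release": "concentration_rate",
}


@dataclass
class TransportSpeciesParameters:
    """Coefficients of one transported species (oxygen or VEGF)."""

    diffusivity: float  # um^2/s
    vessel_permeability: float  # rho, 1/s on occupied sites
    vascular_concentration: float = 0.0  # c_b, nM
    decay: float = 0.0  # lambda, 1/s


@dataclass
class AngioConfig:
    """Plain config mirror of AngiogenesisParameters (kept unnormalized)."""

    p_max: float = 1e-5
    c_50: float = 0.5
    tip_speed: float = 20.0 / 3600.0
    persistence_weight: float = 0.5
    chemotaxis_weight: float = 0.3
    vessel_attraction_weight: float = 0.1
    noise_weight: float = 0.1
    attraction_radius: float = 50.0
    anastomosis_radius: float = 5.0
    sprout_exclusion_distance: float = 40.0
    sprout_radius: float = 5.0

    def build(self):
        from .angiogenesis import AngiogenesisParameters

        return AngiogenesisParameters(**asdict(self))


@dataclass
class SimulationConfig:
    scenario: str = "tumor"  # tumor | cornea
    seed: int = 0
    grid_spacing: float = 40.0  # um
    dt_global: float = 1800.0  # s (30 min)
    dt_ode: float = 300.0  # s (5 min)
    end_time: float = 90000.0  # s (25 h)
    output_dir: str = "outputs"
    output_cadence: int = 10  # steps between snapshots; 0 = final only

    # hemodynamics
    rheology: RheologyParameters = field(default_factory=RheologyParameters)
    adaptation: AdaptationParameters = field(default_factory=AdaptationParameters)
    adaptation_enabled: bool = True
    inlet_haematocrit: float = 0.45
    phase_separation_law: str = "logit"
    perfusion_threshold: float = 1.0  # um^3/s
    inlet_pressure: float = 3330.0  # Pa
    outlet_pressure: float = 2000.0  # Pa (drop 1.33 kPa)

    # transport
    oxygen: TransportSpeciesParameters = field(
        default_factory=lambda: TransportSpeciesParameters(
            diffusivity=2000.0, vessel_permeability=5.0,
            vascular_concentration=30.0, decay=0.0))
    vegf: TransportSpeciesParameters = field(
        default_factory=lambda: TransportSpeciesParameters(
            diffusivity=100.0, vessel_permeability=0.01,
            vascular_concentration=0.0, decay=1e-3))

    # cells (key: cell type code)
    cell_types: dict = field(default_factory=lambda: {
        TUMOR: CellTypeParameters(
            t_min=28800.0, c_phi=15.0, c_hypoxia=10.0, c_death=1.0,
            t_death=28800.0, k_vegf_release=0.01, k_o2_consumption=0.08),
        NORMAL: CellTypeParameters(
            t_min=86400.0, c_phi=15.0, c_hypoxia=10.0, c_death=3.0,
            t_death=7200.0, k_vegf_release=0.01, k_o2_consumption=0.05),
    })
    tumor_seed_diameter: float = 300.0  # um

    # angiogenesis
    angiogenesis: AngioConfig = field(default_factory=AngioConfig)

    # cornea geometry
    shell_outer_radius: float = 1400.0  # um
    shell_thickness: float = 100.0  # um
    pellet_side: float = 300.0  # um
    pellet_depth: float = 100.0  # um
    pellet_concentration: float = 3.0  # nM
    limbus_nodes: int = 64
    limbus_radius: float = 10.0  # um

    def __post_init__(self):
        if self.scenario not in ("tumor", "cornea"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        n = self.dt_global / self.dt_ode
        if abs(n - round(n)) > 1e-9:
            raise ValueError("dt_ode must divide dt_global")
        m = self.end_time / self.dt_global
        if abs(m - round(m)) > 1e-9:
            raise ValueError("end_time must be a multiple of dt_global")

    @property
    def n_global_steps(self) -> int:
        return int(round(self.end_time / self.dt_global))

    @property
    def n_substeps(self) -> int:
        return int(round(self.dt_global / self.dt_ode))


_TYPE_KEYS = {"tumor": TUMOR, "Tumor": TUMOR, "normal": NORMAL, "Normal": NORMAL,
              TUMOR: TUMOR, NORMAL: NORMAL, str(TUMOR): TUMOR, str(NORMAL): NORMAL}


def _convert(obj, name=None):
    if isinstance(obj, str) and name in _DIMENSIONS:
        return parse_quantity(obj, _DIMENSIONS[name])
    if isinstance(obj, str):
        try:
            return parse_quantity(obj)
        except Exception:
            return obj
    return obj


def _build_dataclass(cls, data: dict):
    kw = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        sub = f.type if isinstance(f.type, type) else None
        if isinstance(v, dict) and f.name == "cell_types":
            kw[f.name] = {
                _TYPE_KEYS[k]: _build_dataclass(CellTypeParameters, {
                    kk: _convert(vv, kk) for kk, vv in tv.items()})
                for k, tv in v.items()
            }
        elif isinstance(v, dict):
            subcls = {
                "rheology": RheologyParameters,
                "adaptation": AdaptationParameters,
                "oxygen": TransportSpeciesParameters,
                "vegf": TransportSpeciesParameters,
                "angiogenesis": AngioConfig,
            }.get(f.name, sub)
            kw[f.name] = _build_dataclass(subcls, {
                kk: _convert(vv, kk) for kk, vv in v.items()})
        else:
            kw[f.name] = _convert(v, f.name)
    return cls(**kw)


def load_config(path_or_dict) -> SimulationConfig:
    """Load a config from a YAML file path or a plain dict."""
    if isinstance(path_or_dict, dict):
        data = path_or_dict
    else:
        data = yaml.safe_load(Path(path_or_dict).read_text())
        if data is None:
            data = {}
    return _build_dataclass(SimulationConfig, data)


def _to_plain(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def save_config(config: SimulationConfig, path) -> None:
    """Echo the fully resolved config (internal units) as YAML."""
    Path(path).write_text(yaml.safe_dump(_to_plain(config), sort_keys=False))


def default_tumor_config(**overrides) -> SimulationConfig:
    cfg = {"scenario": "tumor"}
    cfg.update(overrides)
    return load_config(cfg)


def default_cornea_config(**overrides) -> SimulationConfig:
    # Avascular cornea: no vessel sink, and slow VEGF clearance so the
    # pellet's field spans the tissue and reaches the limbus (the decay
    # length sqrt(D/lambda) exceeds the cornea radius), as in the assay.
    cfg = {
        "scenario": "cornea",
        "vegf": {"diffusivity": 100.0, "vessel_permeability": 0.0,
                 "decay": 1e-5},
    }
    for k, v in overrides.items():
        if k == "vegf" and isinstance(v, dict):
            cfg["vegf"].update(v)
        else:
            cfg[k] = v
    return load_config(cfg)
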