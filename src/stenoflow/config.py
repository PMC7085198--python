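"""Configuration loading, validation and the run manifest.

Config files are YAML with the blocks ``geometry``, ``fluid``, ``porous``,
``waveform`` and ``simulation``.  File units follow clinical/bench habit —
lengths in mm, microvessel diameter in µm, velocities in m/s, pressures in
Pa, times in s — and are converted to strict SI on load.  Every key has a
default reproducing the reference 75%-stenosis microcirculation-load case,
so an empty file (or ``{}``) is a complete, runnable configuration.
"""

from __future__ import annotations

import importlib.metadata
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .constitutive import CarreauParams, FluidParams, PorousParams, permeability
from .errors import ConfigurationError
from .geometry import StenosisGeometry, area_stenosis
from .solver import SimulationConfig
from .waveform import InletWaveform, build_waveform, period_from_heart_rate

__all__ = ["ResolvedConfig", "RunManifest", "load_config", "default_config_dict"]

_GEOMETRY_KEYS = {"r_p_mm", "r_s_mm", "r_d_mm", "l_c_mm", "l_s_mm", "l_d_mm",
                  "L_prox_mm", "L_dist_mm", "L_porous_mm", "nz_per_mm", "nr"}
_FLUID_KEYS = {"rho", "mu0", "mu_inf", "lambda", "n"}
_POROUS_KEYS = {"porosity", "d_micro_um", "eta"}
_WAVEFORM_KEYS = {"v_max", "v_mean", "v_min", "heart_rate_bpm", "period_s",
                  "shape", "radial_profile"}
_SIM_KEYS = {"outlet_mode", "outlet_pressure_pa", "dt_s", "steps_per_cycle",
             "n_cycles", "residual_tol", "probe_planes_mm", "wall_bc",
             "snapshot_every"}


def default_config_dict() -> dict:
    """The fully materialized default configuration (file units)."""
    return {
        "geometry": {"r_p_mm": 1.4, "r_s_mm": 0.7, "r_d_mm": 1.4,
                     "l_c_mm": 1.5, "l_s_mm": 1.2, "l_d_mm": 3.0,
                     "L_prox_mm": 14.0, "L_dist_mm": 14.0, "L_porous_mm": None,
                     "nz_per_mm": 4.0, "nr": 32},
        "fluid": {"rho": 1060.0, "mu0": 0.0560, "mu_inf": 0.00345,
                  "lambda": 3.313, "n": 0.3568},
        "porous": {"porosity": 0.5, "d_micro_um": 100.0, "eta": "mu_inf"},
        "waveform": {"v_max": 0.46, "v_mean": 0.28, "v_min": 0.13,
                     "heart_rate_bpm": 75.0, "period_s": None,
                     "shape": "piecewise-cosine", "radial_profile": "parabolic"},
        "simulation": {"outlet_mode": "ML", "outlet_pressure_pa": None,
                       "dt_s": 0.0032, "steps_per_cycle": 247, "n_cycles": 3,
                       "residual_tol": 1e-5, "probe_planes_mm": None,
                       "wall_bc": "noslip", "snapshot_every": 0},
    }

# Porous segment length when the microcirculation load is present and the
# user does not override it: chosen so that the bed's Darcy resistance at
# the cycle-mean flow puts the mean distal coronary pressure near the
# physiological ~3.5 kPa (26 mmHg) operating point.
DEFAULT_L_POROUS_MM = 0.2


@dataclass(frozen=True)
class ResolvedConfig:
    """All run inputs materialized in SI units."""

    geom: StenosisGeometry
    carreau: CarreauParams
    fluid: FluidParams
    porous: PorousParams | None
    waveform: InletWaveform
    sim: SimulationConfig
    raw: dict = field(repr=False, default_factory=dict)

    @property
    def derived(self) -> dict:
        """Echoed derived quantities (never user-settable)."""
        out = {"area_stenosis_pct": area_stenosis(self.geom)}
        if self.porous is not None:
            out["permeability_m2"] = permeability(self.porous)
        return out


def _check_keys(block: dict, allowed: set, name: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) in {name} block: {sorted(unknown)}")


def _merge(defaults: dict, user: dict) -> dict:
    out = dict(defaults)
    out.update(user)
    return out


def load_config(path_or_dict) -> ResolvedConfig:
    """Load and resolve a configuration from a YAML file path (or a dict).

    Unspecified keys take the reference-case defaults; units are converted
    to SI; cross-field consistency (outlet mode vs porous segment, waveform
    ordering) is validated with descriptive errors.
    """
    if isinstance(path_or_dict, dict):
        user = path_or_dict
    else:
        text = Path(path_or_dict).read_text()
        user = yaml.safe_load(text) or {}
        if not isinstance(user, dict):
            raise ConfigurationError(f"config root must be a mapping: {path_or_dict}")
    _check_keys(user, {"geometry", "fluid", "porous", "waveform", "simulation"},
                "top-level")

    d = default_config_dict()
    g = _merge(d["geometry"], user.get("geometry", {}))
    f = _merge(d["fluid"], user.get("fluid", {}))
    po = _merge(d["porous"], user.get("porous", {}))
    w = _merge(d["waveform"], user.get("waveform", {}))
    s = _merge(d["simulation"], user.get("simulation", {}))
    _check_keys(g, _GEOMETRY_KEYS, "geometry")
    _check_keys(f, _FLUID_KEYS, "fluid")
    _check_keys(po, _POROUS_KEYS, "porous")
    _check_keys(w, _WAVEFORM_KEYS, "waveform")
    _check_keys(s, _SIM_KEYS, "simulation")

    mode = s["outlet_mode"]
    if mode not in ("ML", "PL"):
        raise ConfigurationError(f"outlet_mode must be ML or PL, got {mode!r}")

    L_porous_mm = g["L_porous_mm"]
    explicit_L = "geometry" in user and "L_porous_mm" in user["geometry"]
    if L_porous_mm is None:
        L_porous_mm = DEFAULT_L_POROUS_MM if mode == "ML" else 0.0
    if mode == "PL" and L_porous_mm > 0.0:
        raise ConfigurationError(
            "outlet_mode=PL is a constant-pressure outlet without a porous "
            f"segment, but L_porous_mm={L_porous_mm}; set it to 0 or use ML")
    if mode == "ML" and L_porous_mm <= 0.0:
        raise ConfigurationError(
            "outlet_mode=ML needs a porous segment (L_porous_mm > 0)"
            + ("" if explicit_L else " — internal default error"))

    geom = StenosisGeometry(
        r_p=g["r_p_mm"] * 1e-3, r_s=g["r_s_mm"] * 1e-3, r_d=g["r_d_mm"] * 1e-3,
        l_c=g["l_c_mm"] * 1e-3, l_s=g["l_s_mm"] * 1e-3, l_d=g["l_d_mm"] * 1e-3,
        L_prox=g["L_prox_mm"] * 1e-3, L_dist=g["L_dist_mm"] * 1e-3,
        L_porous=L_porous_mm * 1e-3)

    carreau = CarreauParams(mu0=f["mu0"], mu_inf=f["mu_inf"],
                            lambda_t=f["lambda"], n_index=f["n"])
    fluid = FluidParams(density=f["rho"])
    porous = (PorousParams(porosity=po["porosity"],
                           d_micro=po["d_micro_um"] * 1e-6)
              if mode == "ML" else None)

    if w["period_s"] is not None:
        period = float(w["period_s"])
    else:
        period = period_from_heart_rate(float(w["heart_rate_bpm"]))
    waveform = build_waveform(v_max=w["v_max"], v_mean=w["v_mean"],
                              v_min=w["v_min"], period=period, shape=w["shape"])

    probes = s["probe_planes_mm"]
    if probes is not None:
        probes = tuple(float(p) * 1e-3 for p in probes)
    sim = SimulationConfig(
        dt=s["dt_s"], steps_per_cycle=int(s["steps_per_cycle"]),
        n_cycles=int(s["n_cycles"]), residual_tol=float(s["residual_tol"]),
        outlet_mode=mode, outlet_pressure=s["outlet_pressure_pa"],
        probe_planes=probes, nz_per_mm=float(g["nz_per_mm"]), nr=int(g["nr"]),
        radial_profile=w["radial_profile"], porous_eta=po["eta"],
        wall_bc=s["wall_bc"], snapshot_every=int(s["snapshot_every"]))

    resolved_raw = {"geometry": {**g, "L_porous_mm": L_porous_mm},
                    "fluid": f, "porous": po, "waveform": {**w, "period_s": period},
                    "simulation": s}
    return ResolvedConfig(geom=geom, carreau=carreau, fluid=fluid,
                          porous=porous, waveform=waveform, sim=sim,
                          raw=resolved_raw)


@dataclass
class RunManifest:
    """Everything needed to reproduce a run: the fully resolved configuration,
    software version, derived-quantity echo, and the output inventory."""

    config: dict
    version: str
    derived: dict
    outputs: list[str] = field(default_factory=list)

    @classmethod
    def from_resolved(cls, rc: ResolvedConfig, outputs=()) -> "RunManifest":
        try:
            version = importlib.metadata.version("stenoflow")
        except importlib.metadata.PackageNotFoundError:
            version = "unknown"
        return cls(config=rc.raw, version=version, derived=dict(rc.derived),
                   outputs=list(outputs))

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(
            {"config": self.config, "version": self.version,
             "derived": self.derived, "outputs": self.outputs},
            sort_keys=False))

    @classmethod
    def load(cls, path) -> "RunManifest":
        data = yaml.safe_load(Path(path).read_text())
        return cls(config=data["config"], version=data["version"],
                   derived=data["derived"], outputs=data.get("outputs", []))
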