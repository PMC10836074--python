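"""Scenario files: structured-text configuration tying the model together.

A scenario bundles model rates, an optional oscillation block, initial
conditions and an integration horizon into a YAML document:

    name: osc_orange
    params: {r_A: 1.8, r_B: 1.0, a_11: 0.1, a_12: 0.1, a_21: 0.1, a_22: 0.1, gamma: 0.0}
    osc:
      omega: 5.0
      r_tilde_A: [{amp: -1.6, harmonic: 1, phase: 1.5707963267948966}]
      r_tilde_B: [{amp: 1.6, harmonic: 1, phase: 1.5707963267948966}]
      gamma_tilde: [{amp: 0.5, harmonic: 1, phase: 0.0}]
    init: {p_A: 0.5, N: 10.0}
    horizon: 150.0

Each oscillation term is amp * sin(harmonic * tau + phase); a cosine is
a sine with phase pi/2.  The bundled fixtures reproduce the reference
parameterisations (the three oscillating coexistence scenarios plus one
representative scenario per exclusion/bistability/failure region).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .oscillation import FourierSeries, Harmonic, OscillatorySpec
from .params import ModelParams, PopulationState

__all__ = ["Scenario", "ScenarioError", "load_scenario", "save_scenario", "make_fixtures"]

_PARAM_FIELDS = ("r_A", "r_B", "a_11", "a_12", "a_21", "a_22", "gamma")


class ScenarioError(ValueError):
    """Schema violation in a scenario file; message carries the field path."""


@dataclass(frozen=True)
class Scenario:
    name: str
    params: ModelParams
    init: PopulationState
    horizon: float
    osc: OscillatorySpec | None = None
    stochastic: dict | None = None
    outputs: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        d = {
            "name": self.name,
            "params": self.params.as_dict(),
            "init": {"p_A": self.init.p_A, "N": self.init.N},
            "horizon": self.horizon,
        }
        if self.osc is not None:
            d["osc"] = {
                "omega": self.osc.omega,
                **{
                    key: [
                        {"amp": t.amplitude, "harmonic": t.harmonic, "phase": t.phase}
                        for t in getattr(self.osc, key).terms
                    ]
                    for key in ("r_tilde_A", "r_tilde_B", "gamma_tilde")
                },
            }
        if self.stochastic is not None:
            d["stochastic"] = dict(self.stochastic)
        if self.outputs:
            d["outputs"] = list(self.outputs)
        return d


def _series_from_list(items, path: str) -> FourierSeries:
    terms = []
    for i, item in enumerate(items or []):
        if not isinstance(item, dict) or "amp" not in item:
            raise ScenarioError(f"{path}[{i}]: expected a mapping with key 'amp'")
        try:
            terms.append(
                Harmonic(
                    amplitude=float(item["amp"]),
                    harmonic=int(item.get("harmonic", 1)),
                    phase=float(item.get("phase", 0.0)),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ScenarioError(f"{path}[{i}]: {exc}") from exc
    return FourierSeries(terms)


def scenario_from_dict(doc: dict) -> Scenario:
    if not isinstance(doc, dict):
        raise ScenarioError("scenario document must be a mapping")
    if "name" not in doc:
        raise ScenarioError("name: missing")
    pd = doc.get("params")
    if not isinstance(pd, dict):
        raise ScenarioError("params: missing or not a mapping")
    missing = [f for f in _PARAM_FIELDS[:-1] if f not in pd]
    if missing:
        raise ScenarioError(f"params: missing fields {missing}")
    try:
        params = ModelParams(**{f: float(pd.get(f, 0.0)) for f in _PARAM_FIELDS})
    except ValueError as exc:
        raise ScenarioError(f"params: {exc}") from exc
    idict = doc.get("init", {})
    try:
        init = PopulationState(p_A=float(idict["p_A"]), N=float(idict["N"]))
    except KeyError as exc:
        raise ScenarioError(f"init.{exc.args[0]}: missing") from exc
    except ValueError as exc:
        raise ScenarioError(f"init: {exc}") from exc
    horizon = float(doc.get("horizon", 100.0))
    if horizon <= 0:
        raise ScenarioError("horizon: must be positive")
    osc = None
    if doc.get("osc"):
        od = doc["osc"]
        if "omega" not in od:
            raise ScenarioError("osc.omega: missing")
        try:
            osc = OscillatorySpec(
                omega=float(od["omega"]),
                r_tilde_A=_series_from_list(od.get("r_tilde_A"), "osc.r_tilde_A"),
                r_tilde_B=_series_from_list(od.get("r_tilde_B"), "osc.r_tilde_B"),
                gamma_tilde=_series_from_list(od.get("gamma_tilde"), "osc.gamma_tilde"),
            )
        except ValueError as exc:
            raise ScenarioError(f"osc: {exc}") from exc
    return Scenario(
        name=str(doc["name"]),
        params=params,
        init=init,
        horizon=horizon,
        osc=osc,
        stochastic=doc.get("stochastic"),
        outputs=tuple(doc.get("outputs", ())),
    )


def load_scenario(path) -> Scenario:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return scenario_from_dict(doc)


def save_scenario(scenario: Scenario, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario.as_dict(), fh, sort_keys=False)


def _osc_block(omega, c1, c2, g_amp):
    """Single-harmonic spec gamma~ = g sin(tau), r~_A = c1 cos(tau), r~_B = c2 cos(tau)."""
    return OscillatorySpec(
        omega=omega,
        r_tilde_A=FourierSeries.cosine(c1),
        r_tilde_B=FourierSeries.cosine(c2),
        gamma_tilde=FourierSeries.sine(g_amp),
    )


def make_fixtures(directory) -> list[Path]:
    """Write the bundled scenario fixtures; returns the file paths.

    Includes the three reference oscillating-coexistence scenarios (the
    blue/orange/green parameterisations: a = 0.1, gamma = 0, omega = 5,
    r_A = 1.8, r_B = 1, gamma~ = 0.5 sin tau, r~_i = c_i cos tau), one
    scenario per region IV/V/VI/NA constructed to land in that region,
    the fixed-environment exclusion scenario, and a fixed-environment
    unbalanced-HGT coexistence scenario.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    base = ModelParams.symmetric(r_A=1.8, r_B=1.0, a=0.1, gamma=0.0)
    init = PopulationState(0.5, 10.0)
    # (xi, kappa) = (0.05*c2, 0.05*c1) for gamma~ = 0.5 sin tau, omega = 5
    specs = {
        "osc_blue": (-1.6, -0.2),     # (xi, kappa) = (-0.01, -0.08), region I
        "osc_orange": (-1.6, 1.6),    # (0.08, -0.08), region II
        "osc_green": (-2.2, 2.2),     # (0.11, -0.11), region III
        "region_iv": (0.4, 1.0),       # (0.05, 0.02): A wins
        "region_v": (1.0, -3.0),       # (-0.15, 0.05): bistable
        "region_vi": (-1.6, -3.0),     # (-0.15, -0.08): B wins
        "region_na": (-6.0, 4.0),      # (0.2, -0.3): averaged abundance diverges
    }
    scenarios = [
        Scenario(
            name=name,
            params=base,
            init=init,
            horizon=150.0,
            osc=_osc_block(5.0, c1, c2, 0.5),
        )
        for name, (c1, c2) in specs.items()
    ]
    scenarios.append(
        Scenario(
            name="fixed_exclusion",
            params=base,
            init=PopulationState(0.5, 1.0),
            horizon=50.0,
            stochastic={"system_size": 10000, "h_0": 0.0, "seed": 0},
        )
    )
    scenarios.append(
        Scenario(
            name="fixed_unbalanced_coexistence",
            params=base.replace(gamma=-0.06),
            init=init,
            horizon=100.0,
        )
    )
    paths = []
    for sc in scenarios:
        path = directory / f"{sc.name}.yaml"
        save_scenario(sc, path)
        paths.append(path)
    return paths
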