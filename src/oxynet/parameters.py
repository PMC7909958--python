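"""Physical constants and the unit system shared by every solver module.

Internal units: lengths in cm, time in s, pressures in mmHg, oxygen volume
in cm^3 O2, flow rates in cm^3/s.  All defaults are mutually consistent in
this system with one exception: the blood viscosity ``mu`` is kept as an
opaque resistance scale.  When every network boundary condition prescribes a
flow rate (the only mode this package supports), the flow solution is
invariant to the absolute value of ``mu`` — only conductance ratios matter.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["PhysParams", "default_params", "load_config", "save_config", "NL_PER_S"]

#: 1 nl/s expressed in cm^3/s.
NL_PER_S = 1e-6


@dataclass
class PhysParams:
    """Physiological parameter set.

    Attributes
    ----------
    D_alpha:
        Tissue oxygen conductivity D*alpha, cm^3 O2 / cm / s / mmHg.
    M0:
        Maximum (oxygen-saturated) consumption rate, cm^3 O2 / cm^3 / s.
    P0:
        Oxygen partial pressure at half-maximal consumption, mmHg.
    C0:
        Oxygen concentration of a fully saturated red blood cell, cm^3 O2/cm^3.
    alpha_b:
        Effective oxygen solubility in plasma, cm^3 O2 / cm^3 / mmHg.
    P50:
        Half-saturation pressure of the Hill dissociation curve, mmHg.
    n_hill:
        Hill exponent of the dissociation curve (dimensionless).
    H_D:
        Discharge hematocrit (dimensionless volume fraction).
    mu:
        Blood viscosity; opaque resistance scale (see module docstring).
    P_b0:
        Blood oxygen partial pressure at network inlets, mmHg.
    """

    D_alpha: float = 6e-10
    M0: float = 1.7e-4
    P0: float = 1.0
    C0: float = 0.5
    alpha_b: float = 3.1e-5
    P50: float = 38.0
    n_hill: float = 2.0
    H_D: float = 0.45
    mu: float = 4.6e-9
    P_b0: float = 100.0

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and v > 0):
                raise ValueError(f"parameter {f.name!r} must be a positive number, got {v!r}")
        if self.n_hill < 1:
            raise ValueError("Hill exponent n_hill must be >= 1")
        if not 0 < self.H_D < 1:
            raise ValueError("discharge hematocrit H_D must lie in (0, 1)")

    def replace(self, **kw) -> "PhysParams":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhysParams":
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown physics parameter(s): {sorted(unknown)}")
        p = cls(**{k: float(v) for k, v in d.items()})
        p.validate()
        return p


def default_params() -> PhysParams:
    """Return the standard retina parameter set.

    H_D = 0.45 is the conventional systemic discharge hematocrit; override
    via config when a vessel-specific value is available.
    """
    return PhysParams()


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON config file.

    Recognized sections: ``physics`` (one key per :class:`PhysParams` field)
    and ``solver`` (keys of :class:`oxynet.coupled.SolverConfig`).  Returns a
    dict with a ``PhysParams`` under "physics" and the raw solver dict.
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if raw is None:
        raw = {}
    out = dict(raw)
    out["physics"] = PhysParams.from_dict(raw.get("physics", {}))
    out.setdefault("solver", {})
    return out


def save_config(path: str | Path, params: PhysParams, solver: dict | None = None) -> None:
    path = Path(path)
    doc = {"physics": params.to_dict()}
    if solver:
        doc["solver"] = dict(solver)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
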