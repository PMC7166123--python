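"""Canonical published parameter sets shipped with the package.

Each set bundles an aggregate inverse-linear logistic velocity fit (point
estimates and standard errors), the residual SD of that fit, the sample
size, the observed amplitude-distribution moments, and the matching
duration-law coefficients.  They serve as generating truths for synthetic
data and as fixtures for validation.

Model parameter sets also serialize to/from flat key-value dictionaries
(see :meth:`mainseq.models.VelocityModelParams.to_dict`).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, Optional

import yaml

from mainseq.errors import ValidationError
from mainseq.models import DurationILLogisticModel, VelocityModelParams
from mainseq.synth import AmplitudeDist, AmplitudeMixture, ScatterSpec

__all__ = ["ParamSet", "available_param_sets", "load_param_set", "scatter_spec"]

def _param_dir():
    return resources.files("mainseq").joinpath("data").joinpath("params")


@dataclass(frozen=True)
class ParamSet:
    """One canonical parameter bundle (see the YAML files under data/params)."""

    name: str
    description: str
    raw: dict

    @property
    def velocity(self) -> Optional[VelocityModelParams]:
        v = self.raw.get("velocity")
        return VelocityModelParams.from_dict(v) if v else None

    @property
    def velocity_se(self) -> Dict[str, float]:
        return dict(self.raw.get("velocity_se", {}))

    @property
    def residual_sd(self) -> Optional[float]:
        v = self.raw.get("residual_sd")
        return float(v) if v is not None else None

    @property
    def n(self) -> Optional[int]:
        v = self.raw.get("n")
        return int(v) if v is not None else None

    @property
    def observed(self) -> Dict[str, float]:
        return dict(self.raw.get("observed", {}))

    @property
    def amplitude_dist(self):
        a = self.raw.get("amplitude")
        if a is None:
            return None
        return _amplitude_from_dict(a)

    def duration_model(self) -> Optional[DurationILLogisticModel]:
        """Duration law with K on the scale recorded in the file (K_over_Va·Va)."""
        d = self.raw.get("duration")
        v = self.velocity
        if d is None or v is None:
            return None
        return DurationILLogisticModel(
            Va=v.Va, A0=v.A0, A1=v.A1, A2=v.A2,
            k0=float(d["k0"]), k1=float(d["k1"]), k2=float(d["k2"]),
            K=float(d["K_over_Va"]) * v.Va,
        )


def _amplitude_from_dict(a: dict):
    kind = a["dist"]
    if kind == "mixture":
        comps = tuple(
            (float(c["weight"]), _amplitude_from_dict({**c, "dist": c["dist"]}))
            for c in a["components"]
        )
        return AmplitudeMixture(components=comps)
    if kind in ("truncnorm", "lognormal"):
        return AmplitudeDist(
            kind=kind, mean=float(a["mean"]), sd=float(a["sd"]),
            min=float(a["min"]), max=float(a["max"]),
        )
    raise ValidationError(f"unknown amplitude distribution {kind!r}")


def available_param_sets() -> list:
    return sorted(p.name[: -len(".yaml")] for p in _param_dir().iterdir() if p.name.endswith(".yaml"))


def load_param_set(name: str) -> ParamSet:
    try:
        text = (_param_dir() / f"{name}.yaml").read_text()
    except FileNotFoundError:
        raise ValidationError(
            f"unknown parameter set {name!r}; available: {available_param_sets()}"
        ) from None
    raw = yaml.safe_load(text)
    return ParamSet(name=raw["name"], description=raw.get("description", ""), raw=raw)


def scatter_spec(name: str, seed: int, n: Optional[int] = None) -> ScatterSpec:
    """Build the generating :class:`ScatterSpec` for a canonical set.

    Defaults reproduce the set's published study conditions (its n,
    residual SD, amplitude distribution and fitted model as ground truth);
    ``n`` may be overridden for scaled-down experiments.
    """
    ps = load_param_set(name)
    if ps.velocity is None or ps.amplitude_dist is None or ps.residual_sd is None:
        raise ValidationError(f"parameter set {name!r} does not define a scatter generator")
    return ScatterSpec(
        n=int(n if n is not None else ps.n),
        generator=ps.velocity,
        noise_sd=ps.residual_sd,
        amplitude_dist=ps.amplitude_dist,
        seed=seed,
    )
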