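"""Model parameters: transition rates and covariate coefficients.

The default values are the published maximum-likelihood estimates from the
Swedish longitudinal NAFLD cohort on which the model was developed.  All
rates are per year.  ``kCC3_fixed`` (the CC-to-F3 back rate) is never
estimated; it is fixed to a small value because that transition was not
observed.  ``age_center`` is the centering constant of the age effect on the
death hazard.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import yaml

#: rate parameters (1/year) estimated from data
RATE_FIELDS = ("k01", "k12", "k23", "k3CC", "kback", "kCCDC", "kdeath")

#: all estimated quantities, in reporting order
ESTIMATED_FIELDS = RATE_FIELDS + ("lambda_death", "k_age", "k_DSTEA", "beta_T2D")


@dataclass(frozen=True)
class ModelParameters:
    """Parameters of the covariate-modified fibrosis progression model.

    Attributes
    ----------
    k01, k12, k23, k3CC
        Forward transition rates F0->F1, F1->F2, F2->F3, F3->CC (1/year),
        each multiplied by ``exp(k_DSTEA * DSTEA) * (1 + beta_T2D * T2D)``.
    kback
        Common backward rate shared by F1->F0, F2->F1, F3->F2 (1/year).
    kCCDC
        CC->DC rate (1/year), covariate-free.
    kdeath
        Baseline death rate at stage F0 and the centering age (1/year).
    lambda_death
        Exponential stage coefficient of the death hazard (per stage).
    k_age
        Exponential age coefficient of the death hazard (per year of age).
    k_DSTEA
        Coefficient of steatosis-grade change on the forward rates.
    beta_T2D
        Fractional increase of forward rates for type-2 diabetes.
    kCC3_fixed
        CC->F3 back rate, fixed (not estimated) to a small positive value.
    age_center
        Age (years) at which the age effect on death equals one.
    """

    k01: float = 0.066
    k12: float = 0.076
    k23: float = 0.078
    k3CC: float = 0.11
    kback: float = 0.061
    kCCDC: float = 0.15
    kdeath: float = 0.071
    lambda_death: float = 0.21
    k_age: float = 0.12
    k_DSTEA: float = 1.8
    beta_T2D: float = 0.36
    kCC3_fixed: float = 1e-6
    age_center: float = 76.9

    def __post_init__(self) -> None:
        for name in RATE_FIELDS + ("kCC3_fixed",):
            v = getattr(self, name)
            if not (v >= 0.0 and v == v and v != float("inf")):
                raise ValueError(f"{name} must be a finite non-negative rate, got {v!r}")
        if not self.beta_T2D > -0.999:
            raise ValueError(f"beta_T2D must exceed -0.999, got {self.beta_T2D!r}")
        for name in ("lambda_death", "k_age", "k_DSTEA", "age_center"):
            v = getattr(self, name)
            if not (v == v and abs(v) != float("inf")):
                raise ValueError(f"{name} must be finite, got {v!r}")

    def replace(self, **changes: float) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in dataclasses.fields(self)}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ModelParameters":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown parameter names: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False), encoding="utf-8"
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParameters":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if not isinstance(data, dict):
            raise ValueError(f"parameter file {path} does not contain a mapping")
        return cls.from_dict(data)


def load_default_parameters() -> ModelParameters:
    """Load the packaged reference parameter set (the cohort estimates)."""
    from importlib.resources import files

    with files("fibroprog.data").joinpath("default_params.yaml").open("r") as fh:
        return ModelParameters.from_dict(yaml.safe_load(fh))


def free_parameters(fixed: Iterable[str] = ()) -> list[str]:
    """Names of parameters to estimate, excluding ``fixed`` ones.

    ``kCC3_fixed`` and ``age_center`` are structural constants and are never
    part of the free set.
    """
    fixed = set(fixed)
    unknown = fixed - set(ESTIMATED_FIELDS) - {"kCC3_fixed", "age_center"}
    if unknown:
        raise ValueError(f"unknown fixed parameter names: {sorted(unknown)}")
    return [name for name in ESTIMATED_FIELDS if name not in fixed]
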