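"""Joint parent-metabolite pharmacokinetic parameterization.

Structural model: tamoxifen is absorbed from a gut depot in a first-order
process with lag time (``ka``, ``tlag``) into a central compartment with
apparent volume ``V_TAM/F``.  From there it is either metabolized to
endoxifen with apparent formation clearance ``CL_23/F`` or eliminated via
all other pathways with apparent clearance ``CL_20/F``; endoxifen occupies
its own central compartment (``V_ENDX/F``) and is eliminated linearly
(``CL_30/F``).

Covariate model: power functions of age and body weight on ``CL_20/F``
(centred at reference covariates) and a fractional-change model of the
CYP2D6 activity-score class on ``CL_23/F`` with reference class AS 2
(``CL_23,i = CL_23,typ * (1 + Delta_AS)``, ``Delta_2 = 0``).

Variability: log-normal interindividual variability on both tamoxifen
clearance pathways, ``CL_i = CL_typ * exp(eta)`` with
``eta ~ N(0, omega^2)``; endoxifen elimination carries no random effect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import yaml

from .population import AS_CLASSES, VirtualPatient, as_class_label

_FIELDS = (
    "ka",
    "tlag",
    "v_tam_f",
    "v_endx_f",
    "cl20_f_typ",
    "cl23_f_typ",
    "cl30_f",
    "theta_age",
    "theta_wt",
    "ref_age",
    "ref_wt",
    "frac_change",
    "omega2_cl20",
    "omega2_cl23",
    "sigma_resid",
    "is_placeholder",
)


@dataclass(frozen=True)
class PKParameters:
    """Structural, covariate and variability parameters of the joint model.

    Units: ``ka`` 1/h, ``tlag`` h, volumes L, clearances L/h, ``ref_age``
    years, ``ref_wt`` kg; ``theta_age``/``theta_wt`` are dimensionless power
    exponents; ``frac_change`` maps each activity-score class to the
    dimensionless fractional change of ``CL_23/F`` versus class 2;
    ``omega2_*`` are variances of the log-scale random effects;
    ``sigma_resid`` is an optional log-scale residual-error SD.

    ``is_placeholder`` flags a parameter set that is not a published
    estimate; the flag propagates into run manifests and report headers.
    """

    ka: float
    tlag: float
    v_tam_f: float
    v_endx_f: float
    cl20_f_typ: float
    cl23_f_typ: float
    cl30_f: float
    theta_age: float
    theta_wt: float
    ref_age: float
    ref_wt: float
    frac_change: Mapping[str, float]
    omega2_cl20: float
    omega2_cl23: float
    sigma_resid: float | None = None
    is_placeholder: bool = False

    def __post_init__(self) -> None:
        for name in ("ka", "v_tam_f", "v_endx_f", "cl20_f_typ", "cl23_f_typ",
                     "cl30_f", "ref_age", "ref_wt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.tlag < 0:
            raise ValueError("tlag must be >= 0")
        for name in ("omega2_cl20", "omega2_cl23"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sigma_resid is not None and self.sigma_resid < 0:
            raise ValueError("sigma_resid must be >= 0 when given")
        fc = {as_class_label(k): float(v) for k, v in dict(self.frac_change).items()}
        if set(fc) != set(AS_CLASSES):
            raise ValueError(
                f"frac_change must define every class {AS_CLASSES}, got {sorted(fc)}"
            )
        if fc["2"] != 0.0:
            raise ValueError("frac_change for the reference class 2 must be 0")
        values = [fc[c] for c in AS_CLASSES]
        if any(1.0 + v <= 0 for v in values):
            raise ValueError("1 + frac_change must stay positive for every class")
        if any(b < a for a, b in zip(values, values[1:])):
            raise ValueError("frac_change must be non-decreasing in class order")
        object.__setattr__(self, "frac_change", fc)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["frac_change"] = dict(self.frac_change)
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "PKParameters":
        unknown = set(data) - set(_FIELDS)
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        missing = set(_FIELDS) - set(data) - {"sigma_resid", "is_placeholder"}
        if missing:
            raise ValueError(f"missing parameter keys: {sorted(missing)}")
        return cls(**data)  # type: ignore[arg-type]


def load_parameters(path) -> PKParameters:
    """Load a PK parameter set from a YAML or JSON file (strict schema)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"parameter file {path} does not hold a mapping")
    return PKParameters.from_dict(data)


def save_parameters(params: PKParameters, path) -> None:
    """Write a parameter set to YAML (or JSON, by file suffix)."""
    path = Path(path)
    data = params.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


@dataclass(frozen=True)
class IndividualPK:
    """Individual-level parameters and the micro-constants of the cascade.

    ``k_tam = (CL_20,i + CL_23,i) / V_TAM`` is the total first-order
    tamoxifen elimination rate; a fraction ``fm = CL_23,i / (CL_20,i +
    CL_23,i)`` of eliminated tamoxifen becomes endoxifen, which leaves with
    ``k_endx = CL_30 / V_ENDX``.
    """

    cl20_i: float
    cl23_i: float
    cl30: float
    ka: float
    tlag: float
    v_tam_f: float
    v_endx_f: float

    def __post_init__(self) -> None:
        if self.cl20_i < 0 or self.cl23_i < 0:
            raise ValueError("individual clearances must be >= 0")
        if self.cl20_i + self.cl23_i <= 0:
            raise ValueError("total tamoxifen clearance must be > 0")

    @property
    def k_tam(self) -> float:
        return (self.cl20_i + self.cl23_i) / self.v_tam_f

    @property
    def k_endx(self) -> float:
        return self.cl30 / self.v_endx_f

    @property
    def fm(self) -> float:
        """Fraction of tamoxifen elimination that forms endoxifen."""
        return self.cl23_i / (self.cl20_i + self.cl23_i)


def individual_clearances(patient: VirtualPatient, params: PKParameters) -> IndividualPK:
    """Individual clearances from covariates, AS class and random effects.

    ``CL_20,i = CL_20,typ * (age/ref_age)^theta_age * (wt/ref_wt)^theta_wt
    * exp(eta_cl20)`` and ``CL_23,i = CL_23,typ * (1 + Delta_AS) *
    exp(eta_cl23)``; endoxifen elimination clearance carries no covariates
    or random effect.
    """
    if patient.age <= 0 or patient.weight <= 0:
        raise ValueError(
            f"patient {patient.patient_id}: non-positive covariates "
            f"(age={patient.age}, weight={patient.weight})"
        )
    import math

    label = as_class_label(patient.activity_score)
    cl20 = (
        params.cl20_f_typ
        * (patient.age / params.ref_age) ** params.theta_age
        * (patient.weight / params.ref_wt) ** params.theta_wt
        * math.exp(patient.eta_cl20)
    )
    cl23 = (
        params.cl23_f_typ
        * (1.0 + params.frac_change[label])
        * math.exp(patient.eta_cl23)
    )
    return IndividualPK(
        cl20_i=cl20,
        cl23_i=cl23,
        cl30=params.cl30_f,
        ka=params.ka,
        tlag=params.tlag,
        v_tam_f=params.v_tam_f,
        v_endx_f=params.v_endx_f,
    )
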