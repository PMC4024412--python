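"""One-compartment IV-bolus structural model with exponential between-subject
variability and a combined (proportional + additive) residual-error model.

The structural prediction for subject *i* at time *t* is

    C_i(t) = (Dose / V_i) * exp(-(CL_i / V_i) * t)

with individual parameters generated from population typical values via
exponential random effects,

    CL_i = theta_cl * exp(eta_cl,i),   V_i = theta_v * exp(eta_v,i),

and observations

    y_ij = f_ij * (1 + eps_prop,ij) + eps_add,ij,

where the eps terms are independent zero-mean normals with variances
``sigma_prop2`` and ``sigma_add2``.  The elimination rate constant Ke_i is
never stored; it is always derived as CL_i / V_i.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PopParams",
    "IndividualParams",
    "predict_conc",
    "individual_from_eta",
    "residual_variance",
]


@dataclass(frozen=True)
class PopParams:
    """Population parameters of the mixed-effects model.

    Parameters
    ----------
    theta_cl : float
        Typical clearance (volume/time), > 0.
    theta_v : float
        Typical volume of distribution (volume), > 0.
    omega_cl2, omega_v2 : float
        Variances of the log-scale random effects eta_CL and eta_V, >= 0.
    sigma_prop2 : float
        Proportional residual-error variance (dimensionless), >= 0.
    sigma_add2 : float
        Additive residual-error variance (concentration^2), >= 0.
    """

    theta_cl: float = 0.35
    theta_v: float = 2.0
    omega_cl2: float = 0.09
    omega_v2: float = 0.09
    sigma_prop2: float = 0.01
    sigma_add2: float = 0.04

    def __post_init__(self) -> None:
        if not (self.theta_cl > 0 and self.theta_v > 0):
            raise ValueError(
                f"typical values must be positive: theta_cl={self.theta_cl}, "
                f"theta_v={self.theta_v}"
            )
        for name in ("omega_cl2", "omega_v2", "sigma_prop2", "sigma_add2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.sigma_prop2 + self.sigma_add2 <= 0:
            raise ValueError("residual variance is identically zero")

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.theta_cl,
                self.theta_v,
                self.omega_cl2,
                self.omega_v2,
                self.sigma_prop2,
                self.sigma_add2,
            ]
        )

    @classmethod
    def from_array(cls, x: np.ndarray) -> "PopParams":
        return cls(*(float(v) for v in x))

    def to_dict(self) -> dict:
        return {
            "theta_cl": self.theta_cl,
            "theta_v": self.theta_v,
            "omega_cl2": self.omega_cl2,
            "omega_v2": self.omega_v2,
            "sigma_prop2": self.sigma_prop2,
            "sigma_add2": self.sigma_add2,
        }


@dataclass(frozen=True)
class IndividualParams:
    """Individual PK parameters together with the random effects that
    produced them (cl = theta_cl*exp(eta_cl), v = theta_v*exp(eta_v))."""

    subject_id: int
    cl: float
    v: float
    eta_cl: float = field(default=0.0)
    eta_v: float = field(default=0.0)

    def __post_init__(self) -> None:
        if not (self.cl > 0 and self.v > 0):
            raise ValueError(
                f"subject {self.subject_id}: cl and v must be positive "
                f"(cl={self.cl}, v={self.v})"
            )

    @property
    def ke(self) -> float:
        """Elimination rate constant, derived on demand as cl / v."""
        return self.cl / self.v


def individual_from_eta(
    pop: PopParams, eta_cl: float, eta_v: float, subject_id: int = 0
) -> IndividualParams:
    """Individual parameters from population typical values and random effects."""
    return IndividualParams(
        subject_id=subject_id,
        cl=pop.theta_cl * math.exp(eta_cl),
        v=pop.theta_v * math.exp(eta_v),
        eta_cl=float(eta_cl),
        eta_v=float(eta_v),
    )


def predict_conc(dose: float, indiv: IndividualParams, t):
    """Concentration of a single IV bolus, C(t) = (Dose/V) exp(-(CL/V) t).

    ``t`` may be a scalar or array of non-negative times.
    """
    if dose <= 0:
        raise ValueError(f"dose must be positive, got {dose}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    c = (dose / indiv.v) * np.exp(-(indiv.cl / indiv.v) * t)
    return float(c) if c.ndim == 0 else c


def residual_variance(pred, pop: PopParams):
    """Variance of an observation given the model prediction.

    Var(y | f) = sigma_prop2 * f**2 + sigma_add2 for the combined error model
    y = f*(1 + eps_p) + eps_a.
    """
    pred = np.asarray(pred, dtype=float)
    if np.any(pred < 0):
        raise ValueError("prediction must be non-negative")
    g = pop.sigma_prop2 * pred**2 + pop.sigma_add2
    return float(g) if g.ndim == 0 else g
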