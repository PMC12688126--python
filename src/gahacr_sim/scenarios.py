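"""Named study scenarios and seeded parameter ensembles.

Everything the other modules need to run is generated here: the default
(DELLA-mimicking) parameter set, the three bundled figure-style scenarios
(variant dynamics plus the two steady-state sweep surfaces), and log-normal
multiplicative parameter ensembles for robustness analysis.  No external
data is required anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ga_network import (
    HILL_COEFFICIENT_FIELDS,
    InvalidParameterError,
    ParameterSet,
    VariantSpec,
)
from .sweep import ParameterAxis

__all__ = [
    "Scenario",
    "ParameterEnsemble",
    "default_parameters",
    "figure1_scenarios",
    "perturb_parameters",
]

#: Default number of points and decade span of a sweep axis (8 log-spaced
#: points covering 1e-2 .. 1e2 times the default value).
SWEEP_AXIS_POINTS = 8
SWEEP_AXIS_DECADES = 2.0

#: Default dynamics grid: long enough for every variant to visibly settle.
DYNAMICS_T_END = 200.0
DYNAMICS_N_POINTS = 401


@dataclass(frozen=True)
class Scenario:
    """A fully self-describing run: rerunning it reproduces identical output.

    ``kind`` is "dynamics" (variant comparison on a time grid) or "sweep"
    (2-D steady-state surface for one variant).
    """

    name: str
    kind: str
    params: ParameterSet
    variant: VariantSpec
    t_end: float = DYNAMICS_T_END
    n_points: int = DYNAMICS_N_POINTS
    axis_x: ParameterAxis | None = None
    axis_y: ParameterAxis | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("dynamics", "sweep"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.kind == "sweep" and (self.axis_x is None or self.axis_y is None):
            raise ValueError("sweep scenarios need both axes")

    def time_grid(self) -> np.ndarray:
        return np.linspace(0.0, self.t_end, self.n_points)

    def to_dict(self) -> dict:
        data: dict = {
            "name": self.name,
            "kind": self.kind,
            "params": self.params.to_dict(),
            "variant": self.variant.to_dict(),
            "t_end": float(self.t_end),
            "n_points": int(self.n_points),
            "seed": int(self.seed),
        }
        if self.axis_x is not None:
            data["axis_x"] = self.axis_x.to_dict()
        if self.axis_y is not None:
            data["axis_y"] = self.axis_y.to_dict()
        return data

    @classmethod
    def from_dict(cls, data: dict) -> "Scenario":
        known = {
            "name",
            "kind",
            "params",
            "variant",
            "t_end",
            "n_points",
            "axis_x",
            "axis_y",
            "seed",
        }
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown scenario keys: {', '.join(unknown)}")
        return cls(
            name=data["name"],
            kind=data["kind"],
            params=ParameterSet.from_dict(data["params"]),
            variant=VariantSpec.from_dict(data["variant"]),
            t_end=float(data.get("t_end", DYNAMICS_T_END)),
            n_points=int(data.get("n_points", DYNAMICS_N_POINTS)),
            axis_x=ParameterAxis.from_dict(data["axis_x"]) if "axis_x" in data else None,
            axis_y=ParameterAxis.from_dict(data["axis_y"]) if "axis_y" in data else None,
            seed=int(data.get("seed", 0)),
        )


@dataclass(frozen=True)
class ParameterEnsemble:
    """Seeded multiplicative perturbations around one base parameter set."""

    base: ParameterSet
    members: tuple[ParameterSet, ...]
    cv: float
    seed: int


def default_parameters() -> ParameterSet:
    """The baseline constants, with the repressor block mimicking DELLA's.

    Transcription, translation, mRNA decay, basal protein decay and
    GA-induced decay of the repressor all equal the corresponding DELLA
    constants; the repression strength sits at the log-midpoint of the
    standard sweep range.
    """
    return ParameterSet()


def figure1_scenarios() -> list[Scenario]:
    """The three bundled scenarios mirroring the model-prediction figures.

    * ``fig1D_dynamics`` — GA4 time courses for the three variants;
    * ``fig1E_sweep`` — steady-state GA4 surface for the non-degradable
      repressor over repression strength x basal degradation rate;
    * ``fig1F_sweep`` — the same surface for the GA-degradable repressor
      over repression strength x GA-induced degradation rate.

    The no-degron surface uses the basal protein decay as its degradation
    axis because that variant has its GA-dependent decay disabled by
    definition.
    """
    params = default_parameters()
    repstr_axis = ParameterAxis.log_around(
        "hacr_repstr", params.hacr_repstr, SWEEP_AXIS_DECADES, SWEEP_AXIS_POINTS
    )
    ga_decay_axis = ParameterAxis.log_around(
        "hacr_ga_decay", params.hacr_ga_decay, SWEEP_AXIS_DECADES, SWEEP_AXIS_POINTS
    )
    basal_decay_axis = ParameterAxis.log_around(
        "hacr_protein_decay",
        params.hacr_protein_decay,
        SWEEP_AXIS_DECADES,
        SWEEP_AXIS_POINTS,
    )
    return [
        Scenario(
            name="fig1D_dynamics",
            kind="dynamics",
            params=params,
            variant=VariantSpec("gahacr", "GA20ox"),
        ),
        Scenario(
            name="fig1E_sweep",
            kind="sweep",
            params=params,
            variant=VariantSpec("no_degron_cr", "GA20ox"),
            axis_x=repstr_axis,
            axis_y=basal_decay_axis,
        ),
        Scenario(
            name="fig1F_sweep",
            kind="sweep",
            params=params,
            variant=VariantSpec("gahacr", "GA20ox"),
            axis_x=repstr_axis,
            axis_y=ga_decay_axis,
        ),
    ]


def perturb_parameters(
    base: ParameterSet, cv: float, n: int, seed: int
) -> ParameterEnsemble:
    """Log-normal multiplicative ensemble around ``base``.

    Every rate/threshold constant is multiplied by an independent log-normal
    factor with median 1 and the given coefficient of variation; Hill
    coefficients and the repression exponent stay fixed.  Log-normal factors
    keep every member positive, which is the natural perturbation for
    positive-scale kinetic constants.  Deterministic given ``seed``.
    """
    if cv < 0:
        raise InvalidParameterError(f"cv must be >= 0, got {cv}")
    if n < 1:
        raise InvalidParameterError(f"ensemble size must be >= 1, got {n}")
    rate_fields = [
        name
        for name in ParameterSet.field_names()
        if name not in HILL_COEFFICIENT_FIELDS
    ]
    if cv == 0:
        return ParameterEnsemble(base, tuple(base for _ in range(n)), 0.0, seed)
    sigma = float(np.sqrt(np.log1p(cv**2)))  # median-1 log-normal with this cv
    rng = np.random.default_rng(seed)
    members = []
    for _ in range(n):
        factors = np.exp(rng.normal(0.0, sigma, size=len(rate_fields)))
        members.append(
            base.replace(
                **{
                    name: getattr(base, name) * f
                    for name, f in zip(rate_fields, factors)
                }
            )
        )
    return ParameterEnsemble(base, tuple(members), float(cv), seed)
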