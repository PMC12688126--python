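"""Gibberellin signaling network with an optional synthetic repressor node.

The model couples the late GA biosynthesis chain (GA12 -> GA15 -> GA24 ->
GA9 -> GA4, the first three oxidations catalyzed by GA20ox and the last by
GA3ox) to the canonical relief-of-repression signaling module: bioactive GA4
binds the GID1 receptor, the GA4.GID1 complex binds the DELLA repressor, and
the ternary complex routes DELLA to degradation.  DELLA closes the
homeostatic loops by activating GA20ox, GA3ox and GID1 transcription and
repressing its own.

On top of this baseline the module adds a GA-regulated Hormone Activated
Cas9-based Repressor (GAHACR): a dCas9-degron-repression-domain fusion whose
mRNA/protein dynamics mirror DELLA's (transcription, translation, basal
decay, and GA4.GID1-complex-mediated decay with its own rate constant) and
whose protein enters the denominator of the Hill function driving its target
promoter, scaled by a repression-strength constant.  Three regulatory
variants are supported: ``wildtype`` (no repressor), ``no_degron_cr`` (the
repressor without GA-dependent degradation), and ``gahacr`` (the full
construct).

All quantities are nondimensional; one time unit is the mRNA half-life scale
(all mRNA decay rates default to 1).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "SPECIES",
    "SPECIES_INDEX",
    "VARIANTS",
    "TARGETS",
    "InvalidParameterError",
    "NumericStateError",
    "ParameterSet",
    "VariantSpec",
    "ModelDefinition",
    "hill_activation",
    "repressed_activation",
    "apply_variant",
    "zero_state",
]


class InvalidParameterError(ValueError):
    """A rate constant, threshold or Hill coefficient violates its domain."""


class NumericStateError(ValueError):
    """A state vector contains NaN/Inf; the message names the species."""


#: Ordered species roster.  ``ga4`` is the primary readout.
SPECIES: tuple[str, ...] = (
    "ga12",
    "ga15",
    "ga24",
    "ga9",
    "ga4",
    "ga20ox_mrna",
    "ga20ox",
    "ga3ox_mrna",
    "ga3ox",
    "gid1_mrna",
    "gid1",
    "della_mrna",
    "della",
    "ga4_gid1",
    "ga4_gid1_della",
    "hacr_mrna",
    "hacr",
)

SPECIES_INDEX: dict[str, int] = {name: i for i, name in enumerate(SPECIES)}

N_SPECIES = len(SPECIES)

VARIANTS = ("wildtype", "no_degron_cr", "gahacr")
TARGETS = ("GA20ox", "GA3ox", "GID1", "none")

#: Species produced only by the synthetic construct.
HACR_SPECIES = ("hacr_mrna", "hacr")


def hill_activation(activator: float, K: float, n: float) -> float:
    """Activating Hill fraction ``a**n / (K**n + a**n)``.

    Parameters
    ----------
    activator : concentration of the transcriptional activator (>= 0).
    K : half-saturation threshold (> 0).
    n : Hill coefficient (>= 1).

    Returns a dimensionless fraction in ``[0, 1)``, strictly increasing in
    ``activator``.
    """
    if K <= 0:
        raise InvalidParameterError(f"Hill threshold K must be > 0, got {K}")
    if n < 1:
        raise InvalidParameterError(f"Hill coefficient n must be >= 1, got {n}")
    if activator < 0:
        raise InvalidParameterError(f"activator must be >= 0, got {activator}")
    a_n = activator**n
    return a_n / (K**n + a_n)


def repressed_activation(
    activator: float,
    repressor: float,
    repstr: float,
    K: float,
    n: float,
    rep_exponent: float = 1.0,
) -> float:
    """Hill activation with a repressor term added to the denominator.

    ``a**n / (K**n + a**n + (repstr * repressor)**q)`` with ``q`` defaulting
    to 1 (linear occlusion of the promoter by the bound repressor).  Reduces
    to :func:`hill_activation` when either ``repressor`` or ``repstr`` is
    zero, decreases monotonically in both, and tends to 0 as the repressor
    grows without bound.
    """
    if repstr < 0:
        raise InvalidParameterError(f"repression strength must be >= 0, got {repstr}")
    if repressor < 0:
        raise InvalidParameterError(f"repressor must be >= 0, got {repressor}")
    if rep_exponent < 1:
        raise InvalidParameterError(
            f"repression exponent must be >= 1, got {rep_exponent}"
        )
    if K <= 0:
        raise InvalidParameterError(f"Hill threshold K must be > 0, got {K}")
    if n < 1:
        raise InvalidParameterError(f"Hill coefficient n must be >= 1, got {n}")
    a_n = activator**n
    return a_n / (K**n + a_n + (repstr * repressor) ** rep_exponent)


# Fields that are Hill coefficients / exponents: excluded from multiplicative
# ensemble perturbation and constrained to >= 1.
HILL_COEFFICIENT_FIELDS = (
    "ga20ox_n",
    "ga3ox_n",
    "gid1_n",
    "della_n",
    "hacr_rep_exponent",
)

# Thresholds must be strictly positive.
THRESHOLD_FIELDS = ("ga20ox_K", "ga3ox_K", "gid1_K", "della_K")


@dataclass(frozen=True)
class ParameterSet:
    """Every rate/threshold constant of the network, GAHACR block included.

    Defaults give a homeostatic baseline with O(1) concentration scales; the
    GAHACR constants default to the corresponding DELLA values (transcription,
    translation, decay, GA-induced decay), with the repression strength at the
    log-midpoint of the standard sweep range.
    """

    # -- GA biosynthesis ---------------------------------------------------
    ga12_synthesis: float = 1.0  # constant GA12 influx from the upstream pathway
    k_ga12_ox: float = 1.0  # GA20ox-catalyzed GA12 -> GA15
    k_ga15_ox: float = 1.0  # GA20ox-catalyzed GA15 -> GA24
    k_ga24_ox: float = 1.0  # GA20ox-catalyzed GA24 -> GA9
    k_ga9_ox: float = 1.0  # GA3ox-catalyzed  GA9  -> GA4
    ga_intermediate_turnover: float = 0.1
    ga4_turnover: float = 1.0

    # -- receptor module ---------------------------------------------------
    ga4_gid1_on: float = 10.0
    ga4_gid1_off: float = 1.0
    ternary_decay: float = 1.0  # GA4.GID1.DELLA -> GA4.GID1 (DELLA degraded)

    # -- GA20ox transcription unit (DELLA-activated) -----------------------
    ga20ox_tx: float = 1.0
    ga20ox_K: float = 1.0
    ga20ox_n: float = 2.0
    ga20ox_mrna_decay: float = 1.0
    ga20ox_tl: float = 1.0
    ga20ox_decay: float = 0.5

    # -- GA3ox transcription unit (DELLA-activated) ------------------------
    ga3ox_tx: float = 1.0
    ga3ox_K: float = 1.0
    ga3ox_n: float = 2.0
    ga3ox_mrna_decay: float = 1.0
    ga3ox_tl: float = 1.0
    ga3ox_decay: float = 0.5

    # -- GID1 transcription unit (DELLA-activated) -------------------------
    gid1_tx: float = 1.0
    gid1_K: float = 1.0
    gid1_n: float = 2.0
    gid1_mrna_decay: float = 1.0
    gid1_tl: float = 1.0
    gid1_decay: float = 0.5

    # -- DELLA transcription unit (auto-repressed) -------------------------
    della_tx: float = 1.0
    della_K: float = 1.0
    della_n: float = 2.0
    della_mrna_decay: float = 1.0
    della_tl: float = 1.0
    della_decay: float = 0.1  # basal protein decay
    della_ga_decay: float = 10.0  # GA4.GID1-complex-mediated decay

    # -- GAHACR block (defaults mimic DELLA's constants) -------------------
    hacr_tx: float = 1.0
    hacr_tl: float = 1.0
    hacr_mrna_decay: float = 1.0
    hacr_protein_decay: float = 0.1
    hacr_ga_decay: float = 10.0
    hacr_repstr: float = 1.0  # dimensionless repression strength
    hacr_rep_exponent: float = 1.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)) or isinstance(v, bool):
                raise InvalidParameterError(f"{f.name} must be a number, got {v!r}")
            if not np.isfinite(v):
                raise InvalidParameterError(f"{f.name} must be finite, got {v}")
            if v < 0:
                raise InvalidParameterError(f"{f.name} must be >= 0, got {v}")
        for name in HILL_COEFFICIENT_FIELDS:
            if getattr(self, name) < 1:
                raise InvalidParameterError(f"{name} must be >= 1")
        for name in THRESHOLD_FIELDS:
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict[str, float]:
        """Flat name -> value map (lossless)."""
        return {f.name: float(getattr(self, f.name)) for f in dataclasses.fields(self)}

    @classmethod
    def from_dict(cls, data: dict[str, float]) -> "ParameterSet":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise InvalidParameterError(f"unknown parameter keys: {', '.join(unknown)}")
        return cls(**{k: float(v) for k, v in data.items()})

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(cls))

    def replace(self, **overrides: float) -> "ParameterSet":
        known = {f.name for f in dataclasses.fields(self)}
        unknown = sorted(set(overrides) - known)
        if unknown:
            raise InvalidParameterError(f"unknown parameter keys: {', '.join(unknown)}")
        return dataclasses.replace(self, **overrides)


@dataclass(frozen=True)
class VariantSpec:
    """Which regulatory variant runs and which promoter the repressor binds.

    ``wildtype`` carries no repressor, so its target is normalized to
    ``"none"`` regardless of the requested one.
    """

    variant: str = "gahacr"
    target: str = "GA20ox"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise InvalidParameterError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}"
            )
        if self.target not in TARGETS:
            raise InvalidParameterError(
                f"unknown target {self.target!r}; expected one of {TARGETS}"
            )
        if self.variant == "wildtype" and self.target != "none":
            object.__setattr__(self, "target", "none")

    def to_dict(self) -> dict[str, str]:
        return {"variant": self.variant, "target": self.target}

    @classmethod
    def from_dict(cls, data: dict[str, str]) -> "VariantSpec":
        unknown = sorted(set(data) - {"variant", "target"})
        if unknown:
            raise InvalidParameterError(f"unknown variant keys: {', '.join(unknown)}")
        return cls(**data)


def apply_variant(params: ParameterSet, variant: VariantSpec) -> ParameterSet:
    """Return the parameter set realizing a regulatory variant.

    wildtype zeroes the repressor's transcription (its species are also
    forced to zero at simulation setup); no_degron_cr zeroes only the
    GA-dependent degradation constant; gahacr is the identity.
    """
    if variant.variant == "wildtype":
        return params.replace(hacr_tx=0.0)
    if variant.variant == "no_degron_cr":
        return params.replace(hacr_ga_decay=0.0)
    if variant.variant == "gahacr":
        return params
    raise InvalidParameterError(f"unknown variant {variant.variant!r}")


def zero_state() -> np.ndarray:
    """All-zero initial state (the default starting condition)."""
    return np.zeros(N_SPECIES)


def _check_state(y: np.ndarray) -> None:
    y = np.asarray(y, dtype=float)
    if y.shape != (N_SPECIES,):
        raise NumericStateError(
            f"state has length {y.shape}, expected {N_SPECIES} species"
        )
    bad = ~np.isfinite(y)
    if bad.any():
        names = [SPECIES[i] for i in np.flatnonzero(bad)]
        raise NumericStateError(f"non-finite concentration for species: {', '.join(names)}")


# DELLA / GAHACR shared sub-equations.  The synthetic repressor's gene model
# is, term for term, the DELLA gene model evaluated with its own constants:
# production repressed by DELLA protein, first-order mRNA decay, first-order
# translation, basal protein decay, and GA4.GID1-complex-catalyzed protein
# decay.  Keeping them as shared closures makes the structural identity a
# property of the code, not of a test.

def _repressor_gene_mrna_rate(
    mrna: float, della: float, tx: float, K: float, n: float, mrna_decay: float
) -> float:
    return tx * (K**n / (K**n + della**n)) - mrna_decay * mrna


def _repressor_gene_protein_rate(
    protein: float,
    mrna: float,
    complex_c1: float,
    tl: float,
    basal_decay: float,
    ga_decay: float,
) -> float:
    return tl * mrna - basal_decay * protein - ga_decay * complex_c1 * protein


class ModelDefinition:
    """Species roster + parameters + variant, compiled into an ODE RHS.

    The RHS is evaluated with the *effective* parameters (variant already
    applied).  ``readout`` names the primary output species (GA4).
    """

    readout = "ga4"

    def __init__(self, params: ParameterSet, variant: VariantSpec | None = None):
        self.base_params = params
        self.variant = variant if variant is not None else VariantSpec("wildtype", "none")
        self.params = apply_variant(params, self.variant)
        self.species = SPECIES

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ModelDefinition(variant={self.variant.variant!r}, "
            f"target={self.variant.target!r})"
        )

    def prepare_initial_state(self, init: np.ndarray | None) -> np.ndarray:
        """Validate an initial state; wildtype forces the repressor to zero."""
        y = zero_state() if init is None else np.array(init, dtype=float)
        _check_state(y)
        if (y < 0).any():
            names = [SPECIES[i] for i in np.flatnonzero(y < 0)]
            raise InvalidParameterError(
                f"negative initial concentration for: {', '.join(names)}"
            )
        if self.variant.variant == "wildtype":
            for name in HACR_SPECIES:
                y[SPECIES_INDEX[name]] = 0.0
        return y

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        """Time derivative of every species at state ``y``."""
        _check_state(y)
        p = self.params
        (
            ga12,
            ga15,
            ga24,
            ga9,
            ga4,
            m20,
            e20,
            m3,
            e3,
            mg,
            gid1,
            md,
            della,
            c1,
            c2,
            mh,
            hacr,
        ) = y

        target = self.variant.target
        rep = (p.hacr_repstr * hacr) ** p.hacr_rep_exponent

        def activation(K: float, n: float, node: str) -> float:
            num = della**n
            den = K**n + num
            if node == target:
                den += rep
            return num / den

        act20 = activation(p.ga20ox_K, p.ga20ox_n, "GA20ox")
        act3 = activation(p.ga3ox_K, p.ga3ox_n, "GA3ox")
        actg = activation(p.gid1_K, p.gid1_n, "GID1")

        bind = p.ga4_gid1_on * ga4 * gid1
        unbind = p.ga4_gid1_off * c1
        # DELLA capture by the GA4.GID1 complex is committed to degradation:
        # the ternary complex only dissociates by destroying its DELLA.
        della_capture = p.della_ga_decay * c1 * della

        dy = np.empty(N_SPECIES)
        dy[0] = p.ga12_synthesis - p.k_ga12_ox * e20 * ga12 - p.ga_intermediate_turnover * ga12
        dy[1] = p.k_ga12_ox * e20 * ga12 - p.k_ga15_ox * e20 * ga15 - p.ga_intermediate_turnover * ga15
        dy[2] = p.k_ga15_ox * e20 * ga15 - p.k_ga24_ox * e20 * ga24 - p.ga_intermediate_turnover * ga24
        dy[3] = p.k_ga24_ox * e20 * ga24 - p.k_ga9_ox * e3 * ga9 - p.ga_intermediate_turnover * ga9
        dy[4] = p.k_ga9_ox * e3 * ga9 - p.ga4_turnover * ga4 - bind + unbind
        dy[5] = p.ga20ox_tx * act20 - p.ga20ox_mrna_decay * m20
        dy[6] = p.ga20ox_tl * m20 - p.ga20ox_decay * e20
        dy[7] = p.ga3ox_tx * act3 - p.ga3ox_mrna_decay * m3
        dy[8] = p.ga3ox_tl * m3 - p.ga3ox_decay * e3
        dy[9] = p.gid1_tx * actg - p.gid1_mrna_decay * mg
        dy[10] = p.gid1_tl * mg - p.gid1_decay * gid1 - bind + unbind
        dy[11] = _repressor_gene_mrna_rate(
            md, della, p.della_tx, p.della_K, p.della_n, p.della_mrna_decay
        )
        dy[12] = _repressor_gene_protein_rate(
            della, md, c1, p.della_tl, p.della_decay, p.della_ga_decay
        )
        dy[13] = bind - unbind - della_capture + p.ternary_decay * c2
        dy[14] = della_capture - p.ternary_decay * c2
        dy[15] = _repressor_gene_mrna_rate(
            mh, della, p.hacr_tx, p.della_K, p.della_n, p.hacr_mrna_decay
        )
        dy[16] = _repressor_gene_protein_rate(
            hacr, mh, c1, p.hacr_tl, p.hacr_protein_decay, p.hacr_ga_decay
        )
        if not np.isfinite(dy).all():
            names = [SPECIES[i] for i in np.flatnonzero(~np.isfinite(dy))]
            raise NumericStateError(
                f"non-finite derivative for species: {', '.join(names)}"
            )
        return dy
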