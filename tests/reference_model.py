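"""Independent reaction-network transcription of the GA signaling model.

This is the test suite's oracle: the same chemistry written a second time,
in a deliberately different style (a list of elementary reactions with
stoichiometries, summed into per-species flux balances) instead of
hand-assembled per-species equations.  It must never import the package's
RHS.  ``include_repressor=False`` yields the baseline network with no
synthetic repressor at all.
"""

from __future__ import annotations

import numpy as np

SPECIES_ORDER = (
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


def _act(d: float, K: float, n: float, extra: float = 0.0) -> float:
    # written via the reciprocal form to stay algebraically independent of
    # the implementation's d**n / (K**n + d**n + extra)
    if d == 0.0:
        return 0.0
    return 1.0 / (1.0 + (K**n + extra) / d**n)


def _autorep(d: float, K: float, n: float) -> float:
    return 1.0 / (1.0 + (d / K) ** n)


def reference_reactions(p: dict, target: str, include_repressor: bool):
    """Elementary reactions as (rate_function, {species: stoichiometry})."""

    def occlusion(s):
        return (p["hacr_repstr"] * s["hacr"]) ** p["hacr_rep_exponent"]

    def act_node(node, K_key, n_key):
        def rate_input(s):
            extra = occlusion(s) if (include_repressor and node == target) else 0.0
            return _act(s["della"], p[K_key], p[n_key], extra)

        return rate_input

    rxns = [
        (lambda s: p["ga12_synthesis"], {"ga12": +1}),
        (lambda s: p["k_ga12_ox"] * s["ga20ox"] * s["ga12"], {"ga12": -1, "ga15": +1}),
        (lambda s: p["k_ga15_ox"] * s["ga20ox"] * s["ga15"], {"ga15": -1, "ga24": +1}),
        (lambda s: p["k_ga24_ox"] * s["ga20ox"] * s["ga24"], {"ga24": -1, "ga9": +1}),
        (lambda s: p["k_ga9_ox"] * s["ga3ox"] * s["ga9"], {"ga9": -1, "ga4": +1}),
        (lambda s: p["ga_intermediate_turnover"] * s["ga12"], {"ga12": -1}),
        (lambda s: p["ga_intermediate_turnover"] * s["ga15"], {"ga15": -1}),
        (lambda s: p["ga_intermediate_turnover"] * s["ga24"], {"ga24": -1}),
        (lambda s: p["ga_intermediate_turnover"] * s["ga9"], {"ga9": -1}),
        (lambda s: p["ga4_turnover"] * s["ga4"], {"ga4": -1}),
        # receptor binding and DELLA destruction
        (
            lambda s: p["ga4_gid1_on"] * s["ga4"] * s["gid1"],
            {"ga4": -1, "gid1": -1, "ga4_gid1": +1},
        ),
        (
            lambda s: p["ga4_gid1_off"] * s["ga4_gid1"],
            {"ga4_gid1": -1, "ga4": +1, "gid1": +1},
        ),
        (
            lambda s: p["della_ga_decay"] * s["ga4_gid1"] * s["della"],
            {"ga4_gid1": -1, "della": -1, "ga4_gid1_della": +1},
        ),
        (
            lambda s: p["ternary_decay"] * s["ga4_gid1_della"],
            {"ga4_gid1_della": -1, "ga4_gid1": +1},
        ),
        # transcription units
        (
            lambda s, f=act_node("GA20ox", "ga20ox_K", "ga20ox_n"): p["ga20ox_tx"] * f(s),
            {"ga20ox_mrna": +1},
        ),
        (lambda s: p["ga20ox_mrna_decay"] * s["ga20ox_mrna"], {"ga20ox_mrna": -1}),
        (lambda s: p["ga20ox_tl"] * s["ga20ox_mrna"], {"ga20ox": +1}),
        (lambda s: p["ga20ox_decay"] * s["ga20ox"], {"ga20ox": -1}),
        (
            lambda s, f=act_node("GA3ox", "ga3ox_K", "ga3ox_n"): p["ga3ox_tx"] * f(s),
            {"ga3ox_mrna": +1},
        ),
        (lambda s: p["ga3ox_mrna_decay"] * s["ga3ox_mrna"], {"ga3ox_mrna": -1}),
        (lambda s: p["ga3ox_tl"] * s["ga3ox_mrna"], {"ga3ox": +1}),
        (lambda s: p["ga3ox_decay"] * s["ga3ox"], {"ga3ox": -1}),
        (
            lambda s, f=act_node("GID1", "gid1_K", "gid1_n"): p["gid1_tx"] * f(s),
            {"gid1_mrna": +1},
        ),
        (lambda s: p["gid1_mrna_decay"] * s["gid1_mrna"], {"gid1_mrna": -1}),
        (lambda s: p["gid1_tl"] * s["gid1_mrna"], {"gid1": +1}),
        (lambda s: p["gid1_decay"] * s["gid1"], {"gid1": -1}),
        # DELLA gene (auto-repressed)
        (
            lambda s: p["della_tx"] * _autorep(s["della"], p["della_K"], p["della_n"]),
            {"della_mrna": +1},
        ),
        (lambda s: p["della_mrna_decay"] * s["della_mrna"], {"della_mrna": -1}),
        (lambda s: p["della_tl"] * s["della_mrna"], {"della": +1}),
        (lambda s: p["della_decay"] * s["della"], {"della": -1}),
    ]
    if include_repressor:
        rxns += [
            (
                lambda s: p["hacr_tx"] * _autorep(s["della"], p["della_K"], p["della_n"]),
                {"hacr_mrna": +1},
            ),
            (lambda s: p["hacr_mrna_decay"] * s["hacr_mrna"], {"hacr_mrna": -1}),
            (lambda s: p["hacr_tl"] * s["hacr_mrna"], {"hacr": +1}),
            (lambda s: p["hacr_protein_decay"] * s["hacr"], {"hacr": -1}),
            (
                lambda s: p["hacr_ga_decay"] * s["ga4_gid1"] * s["hacr"],
                {"hacr": -1},
            ),
        ]
    return rxns


def reference_rhs(
    y: np.ndarray, params: dict, target: str = "GA20ox", include_repressor: bool = True
) -> np.ndarray:
    """Flux-sum derivative vector from the reaction list."""
    s = dict(zip(SPECIES_ORDER, np.asarray(y, dtype=float)))
    flux = {name: 0.0 for name in SPECIES_ORDER}
    for rate_fn, stoich in reference_reactions(params, target, include_repressor):
        r = rate_fn(s)
        for name, coeff in stoich.items():
            flux[name] += coeff * r
    return np.array([flux[name] for name in SPECIES_ORDER])
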