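"""Network-definition unit and property tests.

The RHS is checked term-by-term against an independently written
reaction-network transcription of the same chemistry (tests/reference_model.py).
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gahacr_sim.ga_network import (
    HACR_SPECIES,
    InvalidParameterError,
    ModelDefinition,
    NumericStateError,
    ParameterSet,
    SPECIES,
    SPECIES_INDEX,
    VariantSpec,
    apply_variant,
    hill_activation,
    repressed_activation,
    zero_state,
)
from conftest import random_states
from reference_model import reference_rhs


class TestHillActivation:
    @pytest.mark.parametrize(
        "activator, K, n, expected",
        [
            (0.0, 1.0, 2.0, 0.0),  # no activator, no activation
            (1.0, 1.0, 2.0, 0.5),  # half-saturation at the threshold
            (3.7, 3.7, 4.0, 0.5),
            (10.0, 1.0, 2.0, 100.0 / 101.0),  # direct evaluation of a**n/(K**n+a**n)
        ],
    )
    def test_canonical_values(self, activator, K, n, expected):
        assert hill_activation(activator, K, n) == pytest.approx(expected, abs=1e-15)

    def test_strictly_increasing_and_bounded(self):
        grid = np.linspace(0.0, 50.0, 200)
        vals = np.array([hill_activation(a, 2.0, 3.0) for a in grid])
        assert np.all(np.diff(vals) > 0)
        assert np.all((vals >= 0) & (vals < 1))

    @pytest.mark.parametrize("K, n", [(0.0, 2.0), (-1.0, 2.0), (1.0, 0.5)])
    def test_invalid_parameters_rejected(self, K, n):
        with pytest.raises(InvalidParameterError):
            hill_activation(1.0, K, n)


class TestRepressedActivation:
    def test_reduces_to_hill_without_repression(self):
        for act in [0.0, 0.3, 2.5]:
            base = hill_activation(act, 1.5, 2.0)
            assert repressed_activation(act, 5.0, 0.0, 1.5, 2.0) == base
            assert repressed_activation(act, 0.0, 7.0, 1.5, 2.0) == base

    def test_monotone_in_repressor_and_strength(self):
        """Non-increasing in repressor and repstr on a 20x20 grid."""
        reps = np.linspace(0.0, 10.0, 20)
        strengths = np.linspace(0.0, 10.0, 20)
        grid = np.array(
            [
                [repressed_activation(1.2, r, s, 1.0, 2.0) for r in reps]
                for s in strengths
            ]
        )
        assert np.all(np.diff(grid, axis=1) <= 0)
        assert np.all(np.diff(grid, axis=0) <= 0)

    def test_vanishes_for_large_repressor(self):
        assert repressed_activation(1.0, 1e12, 1.0, 1.0, 2.0) < 1e-10

    def test_negative_repression_strength_rejected(self):
        with pytest.raises(InvalidParameterError):
            repressed_activation(1.0, 1.0, -0.1, 1.0, 2.0)

    @given(
        act=st.floats(0.0, 10.0),
        rep=st.floats(0.0, 10.0),
        strength=st.floats(0.0, 10.0),
    )
    @settings(deadline=None, max_examples=100)
    def test_always_a_fraction(self, act, rep, strength):
        v = repressed_activation(act, rep, strength, 1.0, 2.0)
        assert 0.0 <= v < 1.0


class TestApplyVariant:
    def test_wildtype_silences_repressor_transcription(self, params):
        assert apply_variant(params, VariantSpec("wildtype", "none")).hacr_tx == 0.0

    def test_no_degron_removes_ga_dependent_decay_only(self, params):
        out = apply_variant(params, VariantSpec("no_degron_cr", "GA20ox"))
        assert out.hacr_ga_decay == 0.0
        changed = {
            k for k in params.field_names() if getattr(out, k) != getattr(params, k)
        }
        assert changed == {"hacr_ga_decay"}

    def test_gahacr_is_identity(self, params):
        assert apply_variant(params, VariantSpec("gahacr", "GA20ox")) == params

    def test_unknown_variant_rejected(self):
        with pytest.raises(InvalidParameterError):
            VariantSpec("super_repressor", "GA20ox")

    def test_wildtype_forces_target_none(self):
        assert VariantSpec("wildtype", "GA20ox").target == "none"


class TestParameterSet:
    def test_round_trips_through_dict(self, params):
        assert ParameterSet.from_dict(params.to_dict()) == params

    def test_unknown_key_named_in_error(self, params):
        with pytest.raises(InvalidParameterError, match="hacr_represion"):
            ParameterSet.from_dict({**params.to_dict(), "hacr_represion": 1.0})

    @pytest.mark.parametrize(
        "bad", [{"della_tx": -1.0}, {"ga20ox_n": 0.5}, {"della_K": 0.0}]
    )
    def test_domain_violations_rejected(self, bad):
        with pytest.raises(InvalidParameterError):
            ParameterSet(**bad)


class TestRHS:
    def test_matches_reaction_network_oracle(self, params, rng):
        """Each derivative equals the independent flux-sum transcription."""
        for variant in ["gahacr", "no_degron_cr"]:
            model = ModelDefinition(params, VariantSpec(variant, "GA20ox"))
            p = model.params.to_dict()
            for y in random_states(rng, 20):
                expected = reference_rhs(y, p, target="GA20ox")
                np.testing.assert_allclose(
                    model.rhs(0.0, y), expected, rtol=0, atol=1e-8
                )

    def test_alternate_targets_match_oracle(self, params, rng):
        for target in ["GA3ox", "GID1"]:
            model = ModelDefinition(params, VariantSpec("gahacr", target))
            p = model.params.to_dict()
            for y in random_states(rng, 5):
                np.testing.assert_allclose(
                    model.rhs(0.0, y),
                    reference_rhs(y, p, target=target),
                    rtol=0,
                    atol=1e-8,
                )

    def test_wildtype_reduces_to_baseline_model(self, params, wildtype_model, rng):
        """With repressor species at zero the RHS is the baseline network's."""
        for y in random_states(rng, 20):
            y = y.copy()
            for name in HACR_SPECIES:
                y[SPECIES_INDEX[name]] = 0.0
            baseline = reference_rhs(
                y, wildtype_model.params.to_dict(), include_repressor=False
            )
            np.testing.assert_allclose(
                wildtype_model.rhs(0.0, y), baseline, rtol=0, atol=1e-12
            )

    def test_zero_repression_strength_leaves_target_unrepressed(self, params, rng):
        free = ModelDefinition(
            params.replace(hacr_repstr=0.0), VariantSpec("gahacr", "GA20ox")
        )
        plain = ModelDefinition(params, VariantSpec("gahacr", "none"))
        for y in random_states(rng, 10):
            np.testing.assert_allclose(
                free.rhs(0.0, y), plain.rhs(0.0, y), rtol=0, atol=1e-14
            )

    def test_nonnegative_derivatives_at_zero_state(self, gahacr_model):
        """No species is consumed below zero: the orthant is forward-invariant."""
        assert np.all(gahacr_model.rhs(0.0, zero_state()) >= 0.0)

    def test_structural_equivalence_with_della_gene(self, params, rng):
        """With DELLA's constants, the repressor gene equations are DELLA's.

        Swapping the (mRNA, protein) values between the DELLA slots and the
        repressor slots must swap the corresponding derivative entries.
        """
        model = ModelDefinition(params, VariantSpec("gahacr", "none"))
        p = params
        assert (
            p.hacr_tx,
            p.hacr_tl,
            p.hacr_mrna_decay,
            p.hacr_protein_decay,
            p.hacr_ga_decay,
        ) == (
            p.della_tx,
            p.della_tl,
            p.della_mrna_decay,
            p.della_decay,
            p.della_ga_decay,
        )
        i_md, i_d = SPECIES_INDEX["della_mrna"], SPECIES_INDEX["della"]
        i_mh, i_h = SPECIES_INDEX["hacr_mrna"], SPECIES_INDEX["hacr"]
        for y in random_states(rng, 10):
            dy = model.rhs(0.0, y)
            # copy DELLA's gene state into the repressor's slots: with equal
            # constants its sub-equations must return DELLA's derivatives
            held = y.copy()
            held[i_mh] = y[i_md]
            held[i_h] = y[i_d]
            dy_held = model.rhs(0.0, held)
            assert dy_held[i_mh] == pytest.approx(dy[i_md], rel=1e-12, abs=1e-15)
            assert dy_held[i_h] == pytest.approx(dy[i_d], rel=1e-12, abs=1e-15)

    def test_nan_state_names_offending_species(self, gahacr_model):
        y = zero_state()
        y[SPECIES_INDEX["ga4"]] = np.nan
        with pytest.raises(NumericStateError, match="ga4"):
            gahacr_model.rhs(0.0, y)

    def test_species_roster_unique_and_readout_present(self):
        assert len(set(SPECIES)) == len(SPECIES)
        assert "ga4" in SPECIES
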