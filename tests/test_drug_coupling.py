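"""Mechanism transforms: lamotrigine, benzodiazepines, antipsychotics, blending."""

import math
import random

import numpy as np
import pytest

from catabarrier.drug_coupling import (
    CouplingConfig,
    ParameterTransform,
    antipsychotic_transform,
    apply_regimen,
    benzodiazepine_occupancy,
    benzodiazepine_transform,
    competitive_occupancy,
    competitive_occupancy_bisect,
    control_occupancy,
    lamotrigine_transform,
    provenance_log,
    receptor_effect,
    regimen_transform,
)
from catabarrier.errors import RegimeError
from catabarrier.model_core import PARAM_NAMES, ModelParams, compute_barrier
from catabarrier.pharmacokinetics import Regimen
from catabarrier.registry import BenzoConstants, LamotrigineConstants, default_registry


class TestLamotrigine:
    def test_zero_concentration_is_identity(self):
        assert lamotrigine_transform(0.0).is_identity(tol=1e-14)

    def test_sodium_block_at_half_saturation(self):
        # C = K_C: dI_Na = 1 - 0.5^0.9, E_Na = 1 - 0.15*0.5^0.9 -> theta1
        # factor 1/E_Na ~ 1.0874 (hand-evaluated)
        t = lamotrigine_transform(513.0)
        na = [f for (_, mech, par, f) in t.provenance
              if mech == "Na_block" and par == "theta1"]
        assert na[0] == pytest.approx(1.0 / (1.0 - 0.15 * 0.5**0.9), rel=1e-12)
        assert na[0] == pytest.approx(1.0874, abs=2e-4)

    def test_linear_mechanisms_saturate_at_250_uM(self):
        # the 0.004/uM laws clamp at zero: E_h = E_glu = 0.85 exactly
        for c in (250.0, 400.0, 1000.0):
            t = lamotrigine_transform(c)
            ih = [f for (_, m, p, f) in t.provenance
                  if m == "Ih_shift" and p == "theta1"][0]
            assert ih == pytest.approx(1.0 / 0.85, rel=1e-12)
            assert t.factors["w11"] == pytest.approx(0.85, rel=1e-12)
            assert t.factors["w10"] == pytest.approx(0.85, rel=1e-12)

    def test_targets_only_excitatory_parameters(self):
        t = lamotrigine_transform(100.0)
        for k in ("mu0", "mu1", "theta0", "w00", "w01"):
            assert t.factors[k] == 1.0
        assert t.factors["theta1"] > 1.0
        assert t.factors["w11"] < 1.0


class TestBenzodiazepine:
    def test_zero_concentration(self):
        assert benzodiazepine_occupancy(0.0) == 0.0

    def test_half_occupancy_concentration(self):
        c_half = 73.89 ** (1.0 / 1.4328)  # ~20.1 ng/g
        assert c_half == pytest.approx(20.14, abs=0.01)
        assert benzodiazepine_occupancy(c_half) == pytest.approx(0.5, rel=1e-10)

    @pytest.mark.parametrize("c", [0.5, 5.0, 20.0, 100.0])
    def test_strictly_increasing(self, c):
        assert benzodiazepine_occupancy(2 * c) > benzodiazepine_occupancy(c)

    def test_transform_targets_inhibitory_weights_only(self):
        t = benzodiazepine_transform(0.5)
        assert t.factors["w00"] == pytest.approx(1.5)
        assert t.factors["w01"] == pytest.approx(1.5)
        for k in ("mu0", "mu1", "theta0", "theta1", "w10", "w11"):
            assert t.factors[k] == 1.0

    def test_occupancy_lowers_barrier(self, baseline, baseline_barrier):
        # blended with the population response factor, as in treatment
        p = apply_regimen(baseline, Regimen({"lorazepam": 2.0}),
                          default_registry())
        assert compute_barrier(p).B < baseline_barrier.B

    def test_per_drug_potency_constants(self, registry):
        # clonazepam is the more potent benzodiazepine: half-occupancy at a
        # lower tissue concentration
        lrz = registry.get("lorazepam").benzo
        clz = registry.get("clonazepam").benzo
        assert clz.B_half < lrz.B_half


class TestCompetitiveOccupancy:
    def test_single_ligand_limit_matches_depletion_quadratic(self):
        # C_B = 0: the cubic must reduce to the exact one-ligand equilibrium
        # with receptor depletion, [RA]^2 - [RA](C_A+R+K_A) + C_A*R = 0
        for K_A, C_A in [(25.0, 37.0), (1000.0, 200.0), (4.0, 3.9), (300.0, 10.0)]:
            a = C_A + 1.0 + K_A
            ra = (a - math.sqrt(a * a - 4.0 * C_A)) / 2.0
            assert competitive_occupancy(K_A, C_A, K_B=1.0, C_B=0.0) == pytest.approx(
                ra, rel=1e-9
            )
            # and approximates the Langmuir isotherm (receptor depletion at
            # R_tot = 1 nM accounts for the residual difference)
            assert competitive_occupancy(K_A, C_A, 1.0, 0.0) == pytest.approx(
                C_A / (C_A + K_A), rel=0.12
            )

    def test_matches_bisection_equilibrium_solver(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            K_A, K_B = rng.uniform(1, 5000, 2)
            C_A, C_B = rng.uniform(0, 2000, 2)
            closed = competitive_occupancy(K_A, C_A, K_B, C_B)
            brute = competitive_occupancy_bisect(K_A, C_A, K_B, C_B)
            assert abs(closed - brute) < 1e-6

    def test_strictly_decreasing_in_competitor(self):
        grid = np.linspace(0.0, 500.0, 40)
        occ = [competitive_occupancy(25.0, 37.0, 120.0, c) for c in grid]
        assert np.all(np.diff(occ) < 0)


class TestReceptorEffects:
    def test_control_condition_is_identity(self):
        for r in ("D1", "D2", "5HT1A", "5HT2A", "M1"):
            assert receptor_effect(r, 0.4, 0.4).is_identity(tol=1e-14)

    def test_d2_blockade_disinhibits_excitatory_weights(self):
        t = receptor_effect("D2", R_oc=0.3, R_con=0.6)  # blockade: R_oc < R_con
        assert t.factors["w11"] > 1.0 and t.factors["w10"] > 1.0
        assert t.factors["mu1"] < 1.0

    def test_m1_blockade_raises_excitatory_threshold(self):
        t = receptor_effect("M1", R_oc=0.01, R_con=0.03)
        assert t.factors["theta1"] > 1.0

    def test_excessive_agonism_rejected(self):
        with pytest.raises(ValueError):
            receptor_effect("D1", R_oc=0.9, R_con=0.3)  # factor would go <= 0

    def test_unknown_receptor(self):
        from catabarrier.errors import UnknownReceptor

        with pytest.raises(UnknownReceptor):
            receptor_effect("H1", 0.3, 0.3)


class TestAntipsychotic:
    def test_zero_dose_is_identity(self, registry):
        t = antipsychotic_transform(registry.get("clozapine"), 0.0,
                                    registry.endogenous)
        assert t.is_identity(tol=1e-9)

    def test_clozapine_dominant_effect_is_excitatory_threshold(self, registry):
        from catabarrier.pharmacokinetics import average_csf_concentration

        spec = registry.get("clozapine")
        c = average_csf_concentration(400.0, spec.pk)
        t = antipsychotic_transform(spec, c, registry.endogenous)
        dev = {k: abs(v - 1.0) for k, v in t.factors.items()}
        assert max(dev, key=dev.get) == "theta1"
        assert t.factors["theta1"] > 1.0

    def test_clozapine_stronger_than_olanzapine_on_threshold(self, registry):
        # equal CSF concentration: clozapine shifts theta1 more
        tone = registry.endogenous
        c = 20.0  # nM
        t_clo = antipsychotic_transform(registry.get("clozapine"), c, tone)
        t_ola = antipsychotic_transform(registry.get("olanzapine"), c, tone)
        assert t_clo.factors["theta1"] > t_ola.factors["theta1"] > 1.0


class TestTransformAlgebra:
    def test_composition_commutes_under_shuffling(self, registry):
        doses = {"clozapine": 300.0, "lamotrigine": 200.0, "clonazepam": 2.0,
                 "lorazepam": 1.0, "olanzapine": 10.0}
        ref = regimen_transform(Regimen(doses), registry)
        rng = random.Random(3)
        for _ in range(5):
            items = list(doses.items())
            rng.shuffle(items)
            t = regimen_transform(Regimen(dict(items)), registry)
            for k in PARAM_NAMES:
                assert t.factors[k] == pytest.approx(ref.factors[k], rel=1e-12)

    def test_factor_floor_warns(self):
        t = ParameterTransform.from_factors({"w11": 0.01}, "x", "test")
        with pytest.warns(UserWarning):
            p = t.apply_raw(ModelParams.baseline())
        assert p.w11 == pytest.approx(8.65 * 0.05)


class TestApplyRegimen:
    def test_empty_regimen_is_noop(self, baseline, registry):
        assert apply_regimen(baseline, Regimen({}), registry) == baseline

    def test_zero_response_factor_is_noop(self, baseline, registry):
        p = apply_regimen(baseline, Regimen({"lorazepam": 4.0}), registry,
                          CouplingConfig(response_factor=0.0))
        assert p == baseline

    def test_uncoupled_drugs_have_no_effect(self, baseline, registry):
        p = apply_regimen(baseline, Regimen({"sertraline": 100.0,
                                             "valproate": 1000.0}), registry)
        assert p == baseline

    def test_regime_guard_raises_on_extreme_regimen(self, baseline, registry):
        crazy = Regimen({"lorazepam": 200.0, "clonazepam": 100.0})
        with pytest.raises(RegimeError):
            apply_regimen(baseline, crazy, registry)

    def test_provenance_log_is_json_serializable(self, registry):
        import json

        log = provenance_log(
            Regimen({"clozapine": 300.0, "clonazepam": 2.0}), registry
        )
        text = json.dumps(log)
        assert "GABA_A_potentiation" in text
        entries = json.loads(text)
        assert all(set(e) == {"drug", "mechanism", "parameter", "factor"}
                   for e in entries)
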