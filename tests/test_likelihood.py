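"""Forward-recursion likelihood vs the latent-path enumeration oracle."""

import numpy as np
import pytest

from mscmr.data import Dataset, EncounterHistory, StudyCalendar
from mscmr.likelihood import (
    RealParameterSet,
    brute_force_loglik,
    dataset_deviance,
    individual_loglik,
    loglik_vector,
    realize_parameters,
)
from mscmr.structure import build_design, parse_label

from conftest import random_history


def random_params(rng, T, mark, fledgling, max_age=None):
    psi = {}
    if fledgling:
        max_age = max_age if max_age is not None else T
        for a in range(1, T - mark + 1):
            psi[a] = float(rng.random()) if a <= max_age else 1.0
    return RealParameterSet(
        phi=rng.random(T - 1),
        p=rng.random(T),
        psi_by_age=psi,
        mark_occasion=mark,
        is_fledgling=fledgling,
    )


class TestForwardVsEnumeration:
    def test_agreement_on_random_pairs(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            T = int(rng.integers(2, 6))
            h = random_history(rng, T, "x")
            params = random_params(rng, T, h.mark_occasion, h.is_fledgling)
            a = individual_loglik(h, params)
            b = brute_force_loglik(h, params)
            assert a == pytest.approx(b, abs=1e-10)

    def test_total_probability_normalizes(self):
        rng = np.random.default_rng(13)
        for _ in range(40):
            T = int(rng.integers(2, 6))
            mark = int(rng.integers(1, T))
            fledgling = bool(rng.integers(2))
            params = random_params(rng, T, mark, fledgling)
            total = 0.0
            for bits in np.ndindex(*([2] * (T - mark))):
                det = [0] * T
                det[mark - 1] = 1
                det[mark:] = list(bits)
                try:
                    h = EncounterHistory(
                        "x", mark, "fledgling" if fledgling else "adult", tuple(det),
                        3.0 if fledgling else None,
                    )
                except ValueError:
                    continue
                total += np.exp(individual_loglik(h, params))
            assert total == pytest.approx(1.0, abs=1e-9)


class TestTrivialCases:
    def test_marked_at_final_occasion_contributes_zero(self):
        h = EncounterHistory("x", 4, "adult", (0, 0, 0, 1))
        params = random_params(np.random.default_rng(1), 4, 4, False)
        assert individual_loglik(h, params) == 0.0

    def test_adult_two_occasions_detected(self):
        h = EncounterHistory("x", 1, "adult", (1, 1))
        params = RealParameterSet(
            phi=np.array([0.5]), p=np.array([0.5, 0.5]), psi_by_age={},
            mark_occasion=1, is_fledgling=False,
        )
        assert individual_loglik(h, params) == pytest.approx(np.log(0.25))

    def test_deterministic_survival_all_ones_history(self):
        T = 5
        h = EncounterHistory("x", 1, "fledgling", (1,) * T, 3.2)
        params = RealParameterSet(
            phi=np.ones(T - 1), p=np.ones(T), psi_by_age={a: 1.0 for a in range(1, T)},
            mark_occasion=1, is_fledgling=True,
        )
        assert individual_loglik(h, params) == pytest.approx(0.0, abs=1e-12)
        assert brute_force_loglik(h, params) == pytest.approx(0.0, abs=1e-12)

    def test_impossible_history_flags_minus_infinity(self):
        h = EncounterHistory("x", 1, "adult", (1, 0, 1))
        params = RealParameterSet(
            phi=np.zeros(2), p=np.full(3, 0.9), psi_by_age={},
            mark_occasion=1, is_fledgling=False,
        )
        assert individual_loglik(h, params) < -600
        assert brute_force_loglik(h, params) < -600

    def test_out_of_range_probability_rejected(self):
        h = EncounterHistory("x", 1, "adult", (1, 1))
        params = RealParameterSet(
            phi=np.array([1.5]), p=np.array([0.5, 0.5]), psi_by_age={},
            mark_occasion=1, is_fledgling=False,
        )
        with pytest.raises(ValueError):
            individual_loglik(h, params)

    def test_enumeration_refuses_long_span(self):
        T = 15
        det = [0] * T
        det[0] = 1
        h = EncounterHistory("x", 1, "adult", tuple(det))
        params = random_params(np.random.default_rng(2), T, 1, False)
        with pytest.raises(ValueError, match="span"):
            brute_force_loglik(h, params)


class TestDatasetDeviance:
    def test_all_marked_at_final_occasion_gives_zero(self):
        cal = StudyCalendar(2003, 3)
        hs = [EncounterHistory(f"a{i}", 3, "adult", (0, 0, 1)) for i in range(5)]
        ds = Dataset(calendar=cal, histories=hs)
        design = build_design(parse_label("phi(a1) p(.) psi(0)"), ds)
        assert dataset_deviance(np.zeros(design.k), design) == pytest.approx(0.0)

    def test_doubling_dataset_doubles_deviance(self, small_sim):
        ds, _ = small_sim
        label = "phi(a2) p(T3) psi(3)"
        d1 = build_design(parse_label(label), ds)
        doubled = Dataset(
            calendar=ds.calendar,
            histories=ds.histories
            + [
                EncounterHistory(
                    h.animal_id + "_b", h.mark_occasion, h.mark_class,
                    h.detections, h.fledging_mass_kg,
                )
                for h in ds.histories
            ],
            year_covariates=ds.year_covariates,
        )
        d2 = build_design(parse_label(label), doubled)
        beta = np.random.default_rng(0).normal(size=d1.k)
        assert dataset_deviance(beta, d2) == pytest.approx(
            2 * dataset_deviance(beta, d1), rel=1e-12
        )

    def test_order_invariance(self, small_sim):
        ds, _ = small_sim
        label = "phi(a2 mass) p(T3) psi(3)"
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(ds.histories))
        shuffled = Dataset(
            calendar=ds.calendar,
            histories=[ds.histories[i] for i in perm],
            year_covariates=ds.year_covariates,
        )
        d1 = build_design(parse_label(label), ds)
        d2 = build_design(parse_label(label), shuffled)
        beta = rng.normal(size=d1.k)
        assert dataset_deviance(beta, d1) == pytest.approx(
            dataset_deviance(beta, d2), rel=1e-12
        )

    def test_vectorized_matches_scalar_recursion(self, small_sim):
        ds, _ = small_sim
        design = build_design(parse_label("phi(a2 mass) p(T3) psi(4 ln)"), ds)
        beta = np.random.default_rng(8).normal(size=design.k)
        ll = loglik_vector(beta, design)
        for i in range(0, len(ds.histories), 37):
            params = realize_parameters(beta, design, i)
            assert ll[i] == pytest.approx(
                individual_loglik(ds.histories[i], params), abs=1e-10
            )


class TestRealizeParameters:
    def test_zero_beta_gives_half(self, small_sim):
        ds, _ = small_sim
        design = build_design(parse_label("phi(a2) p(T3) psi(3)"), ds)
        i = next(j for j, h in enumerate(ds.histories) if h.is_fledgling and h.mark_occasion == 1)
        params = realize_parameters(np.zeros(design.k), design, i)
        assert np.allclose(params.phi, 0.5)
        assert np.allclose(params.p[1:], 0.5)
        assert params.psi_by_age[1] == 0.5

    def test_psi_fixed_above_max(self, small_sim):
        ds, _ = small_sim
        design = build_design(parse_label("phi(a2) p(T3) psi(3)"), ds)
        i = next(j for j, h in enumerate(ds.histories) if h.is_fledgling and h.mark_occasion == 1)
        params = realize_parameters(
            np.random.default_rng(0).normal(size=design.k), design, i
        )
        assert params.psi_by_age[4] == 1.0

    def test_mass_slope_shifts_logit_by_one_per_sd(self, small_sim):
        ds, _ = small_sim
        design = build_design(parse_label("phi(a2 mass) p(T3) psi(3)"), ds)
        beta = np.zeros(design.k)
        beta[design.index_of("phi:mass")] = 1.0
        std = ds.mass_standardizer
        fl = [(j, h) for j, h in enumerate(ds.histories) if h.is_fledgling and h.mark_occasion == 1]
        j0, h0 = fl[0]
        z0 = float(std.standardize_value(h0.fledging_mass_kg))
        phi0 = realize_parameters(beta, design, j0).phi[0]
        from scipy.special import logit

        # fledging-year survival logit equals beta * z(mass) exactly
        assert logit(phi0) == pytest.approx(z0, abs=1e-12)
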