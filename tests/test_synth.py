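import numpy as np
import pytest

from ricdosim import (
    OrganKineticSpec,
    dose_report,
    make_s_value_fixture,
    study_like_specs,
    simulate_binding_assay,
    simulate_biodist,
)
from ricdosim.errors import ValidationError
from ricdosim.synth import DEFAULT_DILUTION_SERIES_NM, load_kinetic_specs


class TestOrganKineticSpec:
    def test_uptake_must_exceed_washout(self):
        with pytest.raises(ValidationError):
            OrganKineticSpec("tumour", "uptake_washout", {"a": 1.0, "ku": 0.01, "kw": 0.02})

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValidationError):
            OrganKineticSpec(
                "blood", "biexponential_decline",
                {"a1": -1.0, "k1": 0.1, "a2": 1.0, "k2": 0.01},
            )

    def test_unknown_model(self):
        with pytest.raises(ValidationError):
            OrganKineticSpec("blood", "monoexp", {})

    def test_study_like_curve_values(self):
        by_organ = {s.organ: s for s in study_like_specs()}
        assert by_organ["blood"].true_pct_id_per_g(6.0) == pytest.approx(10.6, rel=0.01)
        assert by_organ["blood"].true_pct_id_per_g(48.0) == pytest.approx(1.9, rel=0.01)
        tumour = by_organ["tumour"]
        assert tumour.true_pct_id_per_g(24.0) > tumour.true_pct_id_per_g(6.0)
        assert tumour.true_pct_id_per_g(24.0) > tumour.true_pct_id_per_g(48.0)


class TestSimulateBiodist:
    def test_zero_noise_matches_model_exactly(self):
        specs = study_like_specs(noise_cv=0.0)
        ms = simulate_biodist(specs, seed=1)
        by = {s.organ: s for s in specs}
        for m in ms:
            assert m.pct_id_per_g == pytest.approx(
                by[m.organ].true_pct_id_per_g(m.time_h), rel=1e-12
            )

    def test_same_seed_is_deterministic(self):
        specs = study_like_specs(noise_cv=0.1)
        assert simulate_biodist(specs, seed=42) == simulate_biodist(specs, seed=42)

    def test_different_seeds_differ(self):
        specs = study_like_specs(noise_cv=0.1)
        assert simulate_biodist(specs, seed=1) != simulate_biodist(specs, seed=2)

    def test_destructive_sampling_layout(self):
        ms = simulate_biodist(study_like_specs(0.1), seed=3, n_per_group=4)
        subjects_by_time = {}
        for m in ms:
            subjects_by_time.setdefault(m.time_h, set()).add(m.subject_id)
        times = list(subjects_by_time)
        for t1 in times:
            for t2 in times:
                if t1 != t2:
                    assert not subjects_by_time[t1] & subjects_by_time[t2]

    def test_large_n_group_means_near_targets(self):
        # law of large numbers: mean-one noise leaves the group mean on the curve
        ms = simulate_biodist(
            study_like_specs(0.1, organs=["blood"]), seed=2024, n_per_group=50
        )
        for t, target in ((6.0, 10.6), (48.0, 1.9)):
            vals = [m.pct_id_per_g for m in ms if m.time_h == t]
            assert np.mean(vals) == pytest.approx(target, rel=0.05)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            simulate_biodist(study_like_specs(), times_h=[], seed=1)
        with pytest.raises(ValidationError):
            simulate_biodist(study_like_specs(), n_per_group=0, seed=1)


class TestSimulateBindingAssay:
    def test_default_series_spans_dilution_range(self):
        assert DEFAULT_DILUTION_SERIES_NM[0] == pytest.approx(0.098)
        assert DEFAULT_DILUTION_SERIES_NM[-1] == pytest.approx(200.7, rel=1e-2)

    def test_zero_noise_specific_binding_is_hyperbola(self):
        obs = simulate_binding_assay(kd_nM=2.9, bmax_pmol=1.83, noise_cv=0.0, seed=0)
        for o in obs:
            sb = o.total_bound_pmol - o.nonspecific_bound_pmol
            expected = 1.83 * o.free_conc_nM / (2.9 + o.free_conc_nM)
            assert sb == pytest.approx(expected, rel=1e-12)

    def test_saturation_limit(self):
        obs = simulate_binding_assay(
            kd_nM=2.9, bmax_pmol=1.83, noise_cv=0.0,
            series_nM=[2.9 * 1000], seed=0, duplicates=1,
        )
        sb = obs[0].total_bound_pmol - obs[0].nonspecific_bound_pmol
        assert sb == pytest.approx(1.83, rel=1e-3)

    def test_duplicates_per_concentration(self):
        obs = simulate_binding_assay(noise_cv=0.05, seed=0, duplicates=2)
        assert len(obs) == 2 * len(DEFAULT_DILUTION_SERIES_NM)

    def test_determinism(self):
        a = simulate_binding_assay(noise_cv=0.05, seed=9)
        b = simulate_binding_assay(noise_cv=0.05, seed=9)
        assert a == b


class TestSValueFixture:
    def test_one_mev_one_gram(self, lu177):
        table, _ = make_s_value_fixture(lu177, {"liver": 1.0}, 1.0)
        assert table.s("liver", "liver") == pytest.approx(1.602176634e-10, rel=1e-9)

    def test_doubling_mass_halves_s(self, lu177):
        table, _ = make_s_value_fixture(lu177, {"a": 1.0, "b": 2.0}, 1.0)
        assert table.s("a", "a") == pytest.approx(2 * table.s("b", "b"), rel=1e-12)

    def test_sphere_curve_strictly_decreasing(self, lu_s_fixture):
        _, curve = lu_s_fixture
        svals = [s for _, s in curve.nodes]
        assert all(s2 < s1 for s1, s2 in zip(svals, svals[1:]))

    def test_labelled_synthetic(self, lu_s_fixture):
        table, _ = lu_s_fixture
        assert "synthetic" in table.phantom_id


class TestEndToEndOracle:
    def test_zero_noise_dose_equals_analytic_energy_deposition(
        self, lu177, organ_masses, noiseless_biodist, lu_s_fixture
    ):
        """Ã·E_mean/m oracle: with S = E/m the computed self-dose must be
        exactly the deposited energy over organ mass."""
        table, sphere = lu_s_fixture
        e_joule = 0.147 * 1.602176634e-13
        tias, report = dose_report(
            noiseless_biodist, lu177, 6.5, table,
            organ_masses=organ_masses, sphere_curve=sphere,
        )
        by_organ = {t.organ: t for t in tias}
        for organ, dose in report.doses_Sv.items():
            if organ in ("tumour", "whole_body"):
                continue
            expected = by_organ[organ].total_Bq_s * e_joule / (organ_masses[organ] * 1e-3)
            assert dose == pytest.approx(expected, rel=1e-9)

    def test_dose_per_mbq_invariant_to_injected_activity(
        self, lu177, organ_masses, noiseless_biodist, lu_s_fixture
    ):
        table, sphere = lu_s_fixture
        _, r1 = dose_report(
            noiseless_biodist, lu177, 1.0, table,
            organ_masses=organ_masses, sphere_curve=sphere,
        )
        _, r2 = dose_report(
            noiseless_biodist, lu177, 10.0, table,
            organ_masses=organ_masses, sphere_curve=sphere,
        )
        for organ in r1.doses_Sv:
            assert r1.doses_Sv_per_MBq[organ] == pytest.approx(
                r2.doses_Sv_per_MBq[organ], rel=1e-12
            )


class TestSpecFiles:
    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "kin.yaml"
        p.write_text(
            "blood:\n"
            "  model: biexponential_decline\n"
            "  parameters: {a1: 4.9, k1: 0.26, a2: 12.1, k2: 0.039}\n"
            "  noise_cv: 0.08\n"
            "tumour:\n"
            "  model: uptake_washout\n"
            "  parameters: {a: 40.0, ku: 0.081, kw: 0.028}\n"
        )
        specs = load_kinetic_specs(p)
        assert {s.organ for s in specs} == {"blood", "tumour"}
        assert specs[0].noise_cv == 0.08
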