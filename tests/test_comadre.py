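import numpy as np
import pytest

from optimmune.comadre import (
    check_matrix,
    collapse_matrix,
    decompose_background_mortality,
    expand_matrix,
    process_ensemble,
    process_matrix,
    read_matrix_directory,
    records_to_frame,
    resize_matrix,
    target_dimension,
)
from optimmune.demography import (
    build_leslie,
    eigen_summary,
    growth_rate,
    leslie_parts,
    life_history_stats,
)
from optimmune.schedules import SCENARIOS, ScenarioSpec
from optimmune.synthetic import EnsembleConfig, generate_leslie_ensemble, write_ensemble

CANONICAL = np.array([[0.0, 1.0], [0.5, 0.5]])


def constant_scenario(ir=0.4, mu_i=0.1, mu_d=0.3, mu_id=0.01):
    return ScenarioSpec(
        name="const", varied_param="ir", start_value=ir, end_value=ir,
        constants={"mu_b": 0.15, "mu_i": mu_i, "mu_d": mu_d, "mu_id": mu_id, "gamma": 4.0},
    )


class TestCheckMatrix:
    def test_canonical_two_class_passes_all(self):
        report = check_matrix(CANONICAL)
        assert report.passed and all(report.checks.values())

    def test_no_return_path_fails_irreducibility(self):
        A = np.array([[0, 1, 0], [0.5, 0, 0], [0, 0.5, 0.2]], dtype=float)
        report = check_matrix(A)
        assert not report.checks["irreducible"]
        assert not report.passed

    def test_interior_diagonal_entry_fails_structure(self):
        A = build_leslie([0, 1, 1], [0.5, 0.5, 0.2])
        A[1, 1] = 0.1
        assert not check_matrix(A).checks["leslie_structure"]

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            check_matrix(np.zeros((2, 3)))


class TestExpand:
    def test_two_to_three_hand_case(self):
        E = expand_matrix(CANONICAL, 3)
        assert np.allclose(E, [[0, 1, 1], [0.5, 0, 0], [0, 0.5, 0.5]])
        assert growth_rate(E) == pytest.approx(growth_rate(CANONICAL), rel=1e-12)

    def test_identity_when_already_at_target(self):
        assert np.array_equal(expand_matrix(CANONICAL, 2), CANONICAL)

    def test_lambda_preserved_on_ensemble(self):
        mats, _ = generate_leslie_ensemble(EnsembleConfig(n=20), seed=5)
        for A in mats:
            lam = growth_rate(A)
            E = expand_matrix(A, A.shape[0] + 4)
            assert abs(growth_rate(E) - lam) / lam < 1e-10

    def test_shrinking_target_rejected(self):
        with pytest.raises(ValueError):
            expand_matrix(expand_matrix(CANONICAL, 4), 3)


class TestCollapse:
    def test_identical_classes_leave_parameters_unchanged(self):
        A = build_leslie([0, 1, 1, 1], [0.5, 0.4, 0.4, 0.4])
        C = collapse_matrix(A, 3)
        F, S = leslie_parts(C)
        assert F == pytest.approx([0, 1, 1])
        assert S == pytest.approx([0.5, 0.4, 0.4])

    def test_inverts_expansion_hand_case(self):
        E = np.array([[0, 1, 1], [0.5, 0, 0], [0, 0.5, 0.5]])
        assert np.allclose(collapse_matrix(E, 2), CANONICAL, atol=1e-12)

    def test_weights_are_stable_age_structure(self):
        A = build_leslie([0, 0.5, 2.0, 1.0], [0.6, 0.7, 0.5, 0.3])
        w = eigen_summary(A).w
        C = collapse_matrix(A, 3)
        F, S = leslie_parts(C)
        wm = w[2:]
        assert F[2] == pytest.approx(wm @ [2.0, 1.0] / wm.sum())
        assert S[2] == pytest.approx(wm @ [0.5, 0.3] / wm.sum())
        assert S[1] == 0.7  # incoming transition unchanged

    def test_lambda_nearly_preserved_on_ensemble(self):
        mats, _ = generate_leslie_ensemble(EnsembleConfig(n=20), seed=5)
        for A in mats:
            if A.shape[0] < 4:
                continue
            lam = growth_rate(A)
            C = collapse_matrix(A, A.shape[0] - 2)
            assert abs(growth_rate(C) - lam) / lam < 0.01

    def test_round_trip_over_identical_appended_classes(self):
        A = CANONICAL
        E = expand_matrix(A, 5)
        assert np.allclose(collapse_matrix(E, 2), A, atol=1e-12)

    @pytest.mark.parametrize("target", [1, 4, 5])
    def test_target_out_of_range(self, target):
        with pytest.raises(ValueError):
            collapse_matrix(build_leslie([0, 1, 1, 1], [0.5] * 4), target)


class TestDecompose:
    def test_forced_by_formula(self):
        A = build_leslie([0, 1], [np.exp(-1.0), np.exp(-1.0)])
        assert decompose_background_mortality(A, 0.75) == pytest.approx([0.75, 0.75])

    def test_half_survival(self):
        A = build_leslie([0, 1], [0.5, 0.5])
        mu = decompose_background_mortality(A, 0.75)
        assert mu == pytest.approx([-0.75 * np.log(0.5)] * 2)
        assert mu[0] == pytest.approx(0.519860, abs=1e-6)

    def test_rho_one_round_trip_identity(self):
        A = build_leslie([0, 0, 2, 1], [0.7, 0.6, 0.5, 0.25])
        mu = decompose_background_mortality(A, 1.0)
        assert np.exp(-mu) == pytest.approx(leslie_parts(A)[1], abs=1e-12)

    def test_zero_terminal_loop_gives_inf_sentinel(self):
        A = build_leslie([0, 2], [0.5, 0.0])
        mu = decompose_background_mortality(A, 0.75)
        assert np.isinf(mu[-1]) and mu[0] == pytest.approx(-0.75 * np.log(0.5))

    def test_zero_interior_survival_excluded(self):
        A = np.array([[0, 1, 1], [0.0, 0, 0], [0, 0.5, 0.2]])
        with pytest.raises(ValueError, match="excluded"):
            decompose_background_mortality(A, 0.75)

    @pytest.mark.parametrize("rho", [0.0, -0.5, 1.5])
    def test_rho_domain(self, rho):
        with pytest.raises(ValueError):
            decompose_background_mortality(CANONICAL, rho)


class TestProcessMatrix:
    def test_matrix_already_at_target_dimension(self):
        # m=2, expectancy 1 + 0.5 + 0.25 = 1.75, target = round(3.75) = 4 = D
        A = build_leslie([0, 1, 1, 1], [0.5, 0.5, 0.5, 0.0])
        stats = life_history_stats(A)
        assert target_dimension(stats) == 4
        rec = process_matrix(A, SCENARIOS["A1"], matrix_id="t")
        assert rec.resize_action == "unchanged"
        assert rec.lam_resized == pytest.approx(rec.lam_orig, rel=1e-12)

    def test_stats_computed_before_resize(self):
        mats, _ = generate_leslie_ensemble(EnsembleConfig(n=5), seed=9)
        for A in mats:
            rec = process_matrix(A, SCENARIOS["B1"], matrix_id="x")
            assert rec.stats_orig == life_history_stats(A)

    def test_flat_risk_gives_demography_independent_optimum(self):
        mats, _ = generate_leslie_ensemble(EnsembleConfig(n=4), seed=11)
        stars = {
            process_matrix(A, constant_scenario(), step=0.01, matrix_id=str(i)).optimum.sp_star
            for i, A in enumerate(mats)
        }
        assert len(stars) == 1

    def test_rho_one_and_zero_risk_reconstructs_resized_survival(self):
        zero_risk = ScenarioSpec(
            name="none", varied_param="ir", start_value=0.0, end_value=0.0,
            constants={"mu_b": 0.0, "mu_i": 0.0, "mu_d": 0.0, "mu_id": 0.0, "gamma": 4.0},
        )
        mats, _ = generate_leslie_ensemble(EnsembleConfig(n=5), seed=13)
        from optimmune.comadre import decompose_background_mortality as dec
        from optimmune.core import survival_probability

        for A in mats:
            stats = life_history_stats(A)
            A2, _ = resize_matrix(A, target_dimension(stats))
            mu_b = dec(A2, 1.0)
            rebuilt = survival_probability(mu_b)
            assert rebuilt == pytest.approx(leslie_parts(A2)[1], abs=1e-12)

    def test_failing_filter_is_reported_by_name(self):
        A = np.array([[0, 1, 0], [0.5, 0, 0], [0, 0.5, 0.2]], dtype=float)
        with pytest.raises(ValueError, match="irreducible"):
            process_matrix(A, SCENARIOS["A1"], matrix_id="bad")


class TestEnsembleIO:
    def test_process_ensemble_excludes_and_reports(self, tmp_path):
        mats, meta = generate_leslie_ensemble(EnsembleConfig(n=3), seed=2)
        bad = np.array([[0, 1, 0], [0.5, 0, 0], [0, 0.5, 0.2]], dtype=float)
        records, report = process_ensemble(
            mats + [bad], list(meta["id"]) + ["bad"], SCENARIOS["A1"], step=0.01
        )
        assert len(records) == 3
        assert not bool(report.loc[report["id"] == "bad", "passed"].item())
        frame = records_to_frame(records)
        assert set(frame.columns) >= {"id", "sp_star", "lam_max", "mean_repro_rate"}

    def test_directory_round_trip(self, tmp_path):
        mats, meta = generate_leslie_ensemble(EnsembleConfig(n=3), seed=2)
        write_ensemble(mats, meta, tmp_path)
        loaded, meta2 = read_matrix_directory(tmp_path, tmp_path / "metadata.csv")
        assert list(meta2["id"]) == list(meta["id"])
        for A, B in zip(mats, loaded):
            assert np.allclose(A, B)
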