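"""Lead-field quality control: correlation indices, flagging, the correction
loop, template fallback and reporting."""

import numpy as np
import pytest

from meegsi import qc as Q
from meegsi.forward import LeadField, SourceSpace
from meegsi.synth import (
    ArtifactSpec,
    inject_artifact,
    make_nested_head,
    proximity_unstable_leadfield_provider,
)


def lf(M, **kw):
    return LeadField(np.asarray(M, dtype=float), **kw)


class TestCorrelations:
    def test_identical_leadfields_correlate_perfectly(self, leadfield_sphere):
        ps, pc, ur, uc = Q.leadfield_correlations(leadfield_sphere, leadfield_sphere)
        assert np.allclose(ps, 1.0) and np.allclose(pc, 1.0)
        assert not ur.any() and not uc.any()

    def test_affine_invariance(self, leadfield_sphere):
        scaled = lf(3.0 * leadfield_sphere.matrix + 5.0)
        ps, pc, _, _ = Q.leadfield_correlations(scaled, leadfield_sphere)
        assert np.allclose(ps, 1.0) and np.allclose(pc, 1.0)

    def test_random_affine_rescalings_preserve_indices(self, leadfield_sphere, leadfield_homogeneous):
        ps0, pc0, _, _ = Q.leadfield_correlations(leadfield_sphere, leadfield_homogeneous)
        rng = np.random.default_rng(0)
        for _ in range(5):
            a, b = rng.uniform(0.1, 10), rng.uniform(-5, 5)
            ps, pc, _, _ = Q.leadfield_correlations(
                lf(a * leadfield_sphere.matrix + b), leadfield_homogeneous
            )
            assert np.allclose(ps, ps0, atol=1e-10)
            assert np.allclose(pc, pc0, atol=1e-10)

    def test_noise_column_detected(self, leadfield_sphere, leadfield_homogeneous):
        corrupted = inject_artifact(
            leadfield_sphere, ArtifactSpec("noise_column", 1.0, targets=(123,), seed=12)
        )
        ps, pc, _, _ = Q.leadfield_correlations(corrupted, leadfield_homogeneous)
        clean_ps, clean_pc, _, _ = Q.leadfield_correlations(leadfield_sphere, leadfield_homogeneous)
        assert abs(pc[123]) < 0.3
        assert np.allclose(np.delete(pc, 123), np.delete(clean_pc, 123))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes"):
            Q.leadfield_correlations(lf(np.zeros((3, 4))), lf(np.zeros((3, 5))))

    def test_zero_variance_column_reported_undefined(self):
        A = np.random.default_rng(1).standard_normal((4, 3))
        B = A.copy()
        B[:, 1] = 7.0  # constant column: correlation undefined
        ps, pc, ur, uc = Q.leadfield_correlations(lf(A), lf(B))
        assert uc[1] and np.isnan(pc[1])


class TestLinearFit:
    def test_pure_scaling(self, leadfield_sphere):
        slope, intercept, r2 = Q.leadfield_linear_fit(lf(2 * leadfield_sphere.matrix), leadfield_sphere)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(1.0)

    def test_snr_ten_gives_expected_r2(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((19, 500))
        noise = rng.standard_normal(X.shape) * np.sqrt(np.var(X) / 10.0)
        _, _, r2 = Q.leadfield_linear_fit(lf(X + noise), lf(X))
        assert r2 == pytest.approx(10.0 / 11.0, abs=0.01)  # R^2 = SNR/(SNR+1)

    def test_constant_baseline_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            Q.leadfield_linear_fit(lf(np.ones((3, 3))), lf(np.ones((3, 3))))


class TestFlagging:
    def make_qc(self, ps, pc):
        qc = Q.QCResult(
            per_sensor_corr=np.asarray(ps, float), per_source_corr=np.asarray(pc, float),
            undefined_rows=np.zeros(len(ps), bool), undefined_cols=np.zeros(len(pc), bool),
        )
        return qc

    def test_all_perfect_passes(self):
        qc = Q.flag_leadfield(self.make_qc([1, 1], [1, 1, 1]), Q.QCThresholds())
        assert qc.status == "pass" and not qc.violated

    def test_sensor_just_below_threshold_flagged(self):
        qc = Q.flag_leadfield(self.make_qc([0.69, 0.9], [0.5, 0.5]), Q.QCThresholds())
        assert qc.status == "flagged"
        assert qc.sensor_flags.tolist() == [True, False]
        assert qc.violated[0]["threshold"] == "sensor_corr_threshold"

    def test_boundary_value_passes_strict_below(self):
        qc = Q.flag_leadfield(self.make_qc([0.70, 0.9], [0.33, 0.5]), Q.QCThresholds())
        assert qc.status == "pass"

    def test_flag_mode_all_requires_both(self):
        thr = Q.QCThresholds(flag_mode="all")
        qc = Q.flag_leadfield(self.make_qc([0.5, 0.9], [0.5, 0.5]), thr)
        assert qc.status == "pass"  # only the sensor mode violates
        qc = Q.flag_leadfield(self.make_qc([0.5, 0.9], [0.1, 0.5]), thr)
        assert qc.status == "flagged"


@pytest.fixture(scope="module")
def loop_fixture(head, source_cap, sensors):
    pos, normals, _, _ = source_cap
    src = SourceSpace(pos, orientations=normals, mode="constrained")
    provider = proximity_unstable_leadfield_provider(seed=2)
    thr = Q.QCThresholds(min_distance_m=0.002, max_iterations=3)
    return head, src, sensors, provider, thr


class TestControlLoop:
    def dented_head(self, head, pos):
        targets = tuple(
            int(np.argmin(np.linalg.norm(head.cortex.vertices - pos[t], axis=1)))
            for t in range(0, 100, 10)
        )
        return inject_artifact(
            head, ArtifactSpec("dent_inner_skull", 0.0005, targets=targets, seed=1)
        )

    def test_clean_fixture_passes_first_iteration(self, loop_fixture):
        head, src, sensors, provider, thr = loop_fixture
        _, _, qc = Q.qc_control_loop(head, src, sensors, provider, thr)
        assert qc.status == "pass"
        assert len(qc.history) == 1

    def test_dented_fixture_corrected_with_monotone_improvement(self, loop_fixture):
        head, src, sensors, provider, thr = loop_fixture
        dented = self.dented_head(head, src.positions)
        fixed_head, L, qc = Q.qc_control_loop(dented, src, sensors, provider, thr)
        assert qc.status == "corrected"
        assert len(qc.history) <= 3
        mins = [h["min_source_corr"] for h in qc.history]
        assert all(a <= b + 1e-12 for a, b in zip(mins, mins[1:]))
        assert qc.history[-1]["min_source_corr"] > qc.history[0]["min_source_corr"]
        assert qc.history[-1]["n_distance_flags"] == 0

    def test_uncorrectable_case_is_incorrigible(self, loop_fixture):
        head, src, sensors, provider, thr = loop_fixture
        dented = self.dented_head(head, src.positions)

        def noisy_provider(h, s, sens):
            L = provider(h, s, sens)
            return inject_artifact(L, ArtifactSpec("noise_column", 1.0, targets=(7,), seed=3))

        one_shot = Q.QCThresholds(min_distance_m=0.002, max_iterations=1)
        _, _, qc = Q.qc_control_loop(dented, src, sensors, noisy_provider, one_shot)
        assert qc.status == "incorrigible"

    def test_deterministic(self, loop_fixture):
        head, src, sensors, provider, thr = loop_fixture
        dented = self.dented_head(head, src.positions)
        _, L1, qc1 = Q.qc_control_loop(dented, src, sensors, provider, thr)
        _, L2, qc2 = Q.qc_control_loop(dented, src, sensors, provider, thr)
        assert np.array_equal(L1.matrix, L2.matrix)
        assert qc1.history == qc2.history

    def test_imported_leadfield_equals_builtin(self, loop_fixture, leadfield_sphere):
        # forward-model agnosticism: a provider returning an "imported" copy
        # of the sphere model gives identical QC results
        head, src, sensors, provider, thr = loop_fixture

        def imported_provider(h, s, sens):
            return LeadField(
                leadfield_sphere.matrix.copy(), provenance="imported",
                sensor_labels=list(leadfield_sphere.sensor_labels),
            )

        def builtin_provider(h, s, sens):
            return leadfield_sphere

        _, _, qa = Q.qc_control_loop(head, src, sensors, imported_provider, thr)
        _, _, qb = Q.qc_control_loop(head, src, sensors, builtin_provider, thr)
        assert np.allclose(qa.per_sensor_corr, qb.per_sensor_corr)
        assert qa.status == qb.status


class TestTemplateFallback:
    def test_default_template_flagged_as_template(self):
        head, src = Q.template_fallback(n_sources=50)
        assert head.provenance == "template"
        assert src.n_sources == 50

    def test_template_leadfield_computable(self, sensors):
        from meegsi.forward import homogeneous_leadfield_eeg

        head, src = Q.template_fallback(n_sources=50)
        L = homogeneous_leadfield_eeg(SourceSpace(src.positions), sensors)
        assert np.all(np.isfinite(L.matrix))

    def test_missing_template_dir_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            Q.template_fallback(str(tmp_path / "nope"))


class TestReport:
    def test_round_trip_and_flag_content(self, tmp_path, leadfield_sphere, leadfield_homogeneous):
        ps, pc, ur, uc = Q.leadfield_correlations(leadfield_sphere, leadfield_homogeneous)
        qc = Q.QCResult(per_sensor_corr=ps, per_source_corr=pc,
                        undefined_rows=ur, undefined_cols=uc,
                        distance_flags=np.zeros(len(pc), bool))
        qc = Q.flag_leadfield(qc, Q.QCThresholds())
        paths = Q.generate_qc_report(qc, str(tmp_path), make_figures=False)
        back = Q.load_qc_report(paths["json"])
        assert np.allclose(back.per_sensor_corr, qc.per_sensor_corr)
        assert back.status == qc.status

    def test_flagged_report_names_threshold(self, tmp_path):
        qc = Q.QCResult(
            per_sensor_corr=np.array([0.5]), per_source_corr=np.array([0.9]),
            undefined_rows=np.zeros(1, bool), undefined_cols=np.zeros(1, bool),
        )
        qc = Q.flag_leadfield(qc, Q.QCThresholds())
        paths = Q.generate_qc_report(qc, str(tmp_path), make_figures=False)
        back = Q.load_qc_report(paths["json"])
        assert back.violated[0]["threshold"] == "sensor_corr_threshold"
        assert back.violated[0]["value"] == 0.7

    def test_pass_report_has_no_flags(self, tmp_path):
        qc = Q.QCResult(
            per_sensor_corr=np.array([0.9]), per_source_corr=np.array([0.9]),
            undefined_rows=np.zeros(1, bool), undefined_cols=np.zeros(1, bool),
        )
        qc = Q.flag_leadfield(qc, Q.QCThresholds())
        paths = Q.generate_qc_report(qc, str(tmp_path), make_figures=False)
        back = Q.load_qc_report(paths["json"])
        assert back.status == "pass" and not back.violated
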