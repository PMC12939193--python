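"""Synthetic cohort generator: templates, Markov switching, cohort files."""

import numpy as np
import pytest

from leida import (
    CohortConfig,
    ConfigurationError,
    TransitionModel,
    fractional_occupancy,
    generate_cohort,
    generate_state_templates,
    occupancy_shift_models,
    simulate_cohort,
    simulate_subject,
    sticky_transition_model,
)
from leida.phase import phase_coherence, instantaneous_phase


class TestStateTemplates:
    def test_unit_norm_and_disjoint_communities(self):
        templates = generate_state_templates(3, 6, seed=1)
        assert len(templates) == 3
        for tpl in templates:
            assert np.linalg.norm(tpl.values) == pytest.approx(1.0, abs=1e-12)
            assert tpl.community == frozenset(
                np.flatnonzero(tpl.values > 0).tolist()
            )
        communities = [tpl.community for tpl in templates]
        for i in range(3):
            for j in range(i + 1, 3):
                assert not (communities[i] & communities[j])
                cos = templates[i].values @ templates[j].values
                assert cos < 0.5

    def test_community_sizes_roughly_equal(self):
        templates = generate_state_templates(4, 90, seed=2)
        sizes = sorted(len(t.community) for t in templates)
        assert sizes == [22, 22, 23, 23]

    def test_seed_reproducibility(self):
        a = generate_state_templates(2, 4, seed=7)
        b = generate_state_templates(2, 4, seed=7)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.values, tb.values)

    @pytest.mark.parametrize("S,N", [(1, 5), (7, 6), (0, 3)])
    def test_invalid_configuration(self, S, N):
        with pytest.raises(ConfigurationError):
            generate_state_templates(S, N, seed=0)


class TestTransitionModel:
    def test_sticky_model_is_row_stochastic_with_target_stationary(self):
        target = np.array([0.5, 0.3, 0.2])
        tm = sticky_transition_model(3, stay=0.7, stationary=target)
        np.testing.assert_allclose(tm.P.sum(axis=1), 1.0, atol=1e-12)
        # independent oracle: stationary distribution via long matrix power
        pi = np.linalg.matrix_power(tm.P, 2000)[0]
        np.testing.assert_allclose(pi, target, atol=1e-10)
        np.testing.assert_allclose(tm.stationary_distribution(), target, atol=1e-10)

    def test_occupancy_shift_models_gap(self):
        tm_a, tm_b = occupancy_shift_models(4, shifted_state=2, gap=0.1)
        pi_a = np.linalg.matrix_power(tm_a.P, 2000)[0]
        pi_b = np.linalg.matrix_power(tm_b.P, 2000)[0]
        assert pi_b[1] - pi_a[1] == pytest.approx(0.1, abs=1e-10)
        assert pi_a.sum() == pytest.approx(1.0)

    def test_invalid_rows_rejected(self):
        with pytest.raises(ConfigurationError):
            TransitionModel(P=np.array([[0.5, 0.4], [0.0, 1.0]]),
                            pi0=np.array([0.5, 0.5]))


class TestSimulateSubject:
    def test_single_global_state_gives_identical_columns(self):
        # one state whose community covers every region: all sinusoids in
        # phase, so downstream coherence is the all-ones matrix
        n = 6
        values = np.ones(n) / np.sqrt(n)
        from leida import StateTemplate

        tpl = StateTemplate(values=values, community=frozenset(range(n)))
        tm = TransitionModel(P=np.ones((1, 1)), pi0=np.ones(1))
        config = CohortConfig(
            n_regions=n, n_volumes=50, n_states=1, noise_sd=0.0,
            group_transition_models=(tm, tm), seed=0,
        )
        ts, labels = simulate_subject(config, tm, [tpl], seed=5)
        for col in range(1, n):
            np.testing.assert_allclose(ts.data[:, col], ts.data[:, 0])
        theta = instantaneous_phase(ts)
        C = phase_coherence(theta[25])
        np.testing.assert_allclose(C, 1.0, atol=1e-9)

    def test_shape_and_reproducibility(self):
        config = CohortConfig(n_per_group=(1, 1), n_volumes=180, seed=3)
        templates = generate_state_templates(4, 90, seed=1)
        tm = sticky_transition_model(4)
        ts1, lab1 = simulate_subject(config, tm, templates, seed=11)
        ts2, lab2 = simulate_subject(config, tm, templates, seed=11)
        assert ts1.data.shape == (180, 90)
        np.testing.assert_array_equal(ts1.data, ts2.data)
        np.testing.assert_array_equal(lab1, lab2)

    def test_empty_templates_rejected(self):
        config = CohortConfig(seed=0)
        tm = sticky_transition_model(4)
        with pytest.raises(ConfigurationError):
            simulate_subject(config, tm, [], seed=0)

    def test_spectral_content_inside_carrier_band(self):
        """Noiseless columns concentrate their spectrum in carrier_band."""
        config = CohortConfig(n_per_group=(1, 1), noise_sd=0.0, seed=13)
        templates = generate_state_templates(4, 90, seed=1)
        tm = sticky_transition_model(4)
        ts, _ = simulate_subject(config, tm, templates, seed=2)
        freqs = np.fft.rfftfreq(ts.n_volumes, d=ts.tr)
        spectrum = np.abs(np.fft.rfft(ts.data, axis=0))
        dominant = freqs[np.argmax(spectrum, axis=0)]
        lo, hi = config.carrier_band
        assert ((dominant >= lo - 1e-9) & (dominant <= hi + 1e-9)).all()


class TestGenerateCohort:
    def test_cohort_directory_contract(self, tmp_path):
        config = CohortConfig(
            n_regions=10, n_volumes=40, n_states=3, n_per_group=(5, 5), seed=4
        )
        manifest = generate_cohort(config, tmp_path / "cohort")
        lines = manifest.read_text().strip().splitlines()
        assert lines[0] == "scan_id\tgroup\tpath"
        assert len(lines) == 11
        groups = [ln.split("\t")[1] for ln in lines[1:]]
        assert groups.count("A") == 5 and groups.count("B") == 5
        truth = manifest.parent / "ground_truth"
        assert (truth / "templates.tsv").exists()
        assert len(list(truth.glob("*_labels.txt"))) == 10

    def test_planted_occupancy_matches_stationary(self):
        """Empirical planted FO over 20 scans tracks the stationary law."""
        tm = sticky_transition_model(3, stay=0.5)
        config = CohortConfig(
            n_regions=6, n_volumes=200, n_states=3, n_per_group=(10, 10),
            noise_sd=0.0, group_transition_models=(tm, tm), seed=8,
        )
        _, _, truths, _ = simulate_cohort(config)
        fo = np.array([fractional_occupancy(t, 3) for t in truths])
        pi = np.linalg.matrix_power(tm.P, 2000)[0]  # independent oracle
        np.testing.assert_allclose(fo.mean(axis=0), pi, atol=0.05)

    def test_null_construction_has_no_expected_gap(self):
        config = CohortConfig(n_per_group=(2, 2), seed=1)
        tm_a, tm_b = config.group_transition_models
        np.testing.assert_array_equal(tm_a.P, tm_b.P)
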