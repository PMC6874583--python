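"""Oddball sequence and synthetic-epoch generator behaviour."""

import numpy as np
import pytest

from trodnet import simulate
from trodnet.montage import channel_index, gaussian_topography
from trodnet.simulate import (
    CONDITIONS,
    N_SAMPLES,
    ONSET_INDEX,
    SFREQ,
    ComponentSpec,
    EffectSpec,
    NoiseParams,
    ParadigmSpec,
    SubjectSpec,
    generate_cohort,
    generate_tone_sequence,
    synth_epoch,
)


def counts(seq):
    vals, cnt = np.unique(seq, return_counts=True)
    return dict(zip(vals.tolist(), cnt.tolist()))


class TestToneSequence:
    def test_default_design_counts(self, default_paradigm):
        """600 tones: 492 standards and 36 of each of three deviants."""
        c = counts(generate_tone_sequence(default_paradigm, seed=1))
        assert c == {"standard": 492, "FDev": 36, "DDev": 36, "IDev": 36}

    def test_degenerate_all_standards(self):
        spec = ParadigmSpec(p_standard=1.0, p_deviant=0.0)
        seq = generate_tone_sequence(spec, seed=0)
        assert counts(seq) == {"standard": 600}

    @pytest.mark.parametrize("m", [1, 3])
    def test_spacing_constraint_holds_on_many_seeds(self, m):
        """Linear scan: no two deviants closer than the minimum spacing."""
        spec = ParadigmSpec(min_standards_between_deviants=m)
        n_seeds = 1000 if m == 1 else 50
        for seed in range(n_seeds):
            seq = generate_tone_sequence(spec, seed=seed)
            dev_pos = np.flatnonzero(seq != "standard")
            assert np.diff(dev_pos).min() >= m + 1

    def test_deterministic_under_seed(self, default_paradigm):
        a = generate_tone_sequence(default_paradigm, seed=42)
        b = generate_tone_sequence(default_paradigm, seed=42)
        assert np.array_equal(a, b)

    def test_infeasible_spacing_raises(self):
        spec = ParadigmSpec(min_standards_between_deviants=5)
        with pytest.raises(ValueError, match="cannot place"):
            generate_tone_sequence(spec, seed=0)

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            ParadigmSpec(p_standard=0.9, p_deviant=0.06)
        with pytest.raises(ValueError, match="integer"):
            ParadigmSpec(n_tones=601)


class TestSynthEpoch:
    def test_shape_and_rate(self, components):
        subj = SubjectSpec(subject_id="s", group="control")
        ep = synth_epoch(subj, "FDev", components, EffectSpec(), NoiseParams(), seed=0)
        assert ep.data.shape == (64, 614)
        assert ep.sfreq == 512.0
        assert N_SAMPLES == int(1.200 * 512)

    def test_null_signal_is_all_zero(self):
        comps = [
            ComponentSpec("P300", 320.0, 55.0, 0.0, gaussian_topography("Pz"))
        ]
        subj = SubjectSpec("s", "control", latency_jitter_ms=0.0, trial_amplitude_sd=0.0)
        ep = synth_epoch(subj, "FDev", comps, EffectSpec(), NoiseParams.none(), seed=0)
        assert np.all(ep.data == 0)

    def test_noiseless_p300_peaks_at_nominal_latency(self):
        """argmax of the closed-form waveform on the topography's peak channel."""
        comps = [ComponentSpec("P300", 310.0, 40.0, 8.0, gaussian_topography("Pz"),
                               conditions=("FDev",))]
        subj = SubjectSpec("s", "control", latency_jitter_ms=0.0, trial_amplitude_sd=0.0)
        ep = synth_epoch(subj, "FDev", comps, EffectSpec(), NoiseParams.none(), seed=0)
        pk = ep.data[channel_index("Pz")].argmax()
        t_peak = (pk - ONSET_INDEX) / SFREQ
        assert abs(t_peak - 0.310) <= 1.5 / SFREQ

    def test_unknown_condition_rejected(self, components):
        subj = SubjectSpec("s", "control")
        with pytest.raises(ValueError, match="condition"):
            synth_epoch(subj, "IDev", components, EffectSpec(), NoiseParams(), seed=0)

    def test_negative_noise_scale_rejected(self):
        with pytest.raises(ValueError):
            NoiseParams(white_scale=-1.0)

    def test_baseline_mean_is_zero_to_storage_precision(self, tiny_cohort):
        for subj in tiny_cohort.subjects[:2]:
            for cond in CONDITIONS:
                base = subj.epochs[cond][:, :, : ONSET_INDEX + 1].mean(axis=-1)
                assert np.abs(base).max() < 1e-5

    def test_deterministic_under_seed(self, components):
        subj = SubjectSpec("s", "concussed")
        a = synth_epoch(subj, "DDev", components, EffectSpec.strong(), NoiseParams(), seed=9)
        b = synth_epoch(subj, "DDev", components, EffectSpec.strong(), NoiseParams(), seed=9)
        assert np.array_equal(a.data, b.data)


def _p300_window_mean(epochs, channel="Pz"):
    """Mean amplitude at the P300 channel in a 280-420 ms window."""
    lo = ONSET_INDEX + int(0.280 * SFREQ)
    hi = ONSET_INDEX + int(0.420 * SFREQ)
    return float(epochs[:, channel_index(channel), lo:hi].mean())


class TestCohort:
    def test_cohort_layout(self, default_paradigm):
        coh = generate_cohort(2, 2, seed=0)
        assert len(coh.subjects) == 4
        for subj in coh.subjects:
            assert subj.epochs["FDev"].shape[0] == 36
            assert subj.epochs["DDev"].shape[0] == 36
            assert subj.epochs["standard"].shape[0] >= 36

    def test_rejection_fraction_reduces_counts(self):
        coh = generate_cohort(1, 1, seed=0, rejection_fraction=0.3)
        for subj in coh.subjects:
            assert subj.epochs["FDev"].shape[0] == round(36 * 0.7)

    def test_group_sizes_validated(self):
        with pytest.raises(ValueError):
            generate_cohort(0, 5)

    def test_attenuation_halves_p300_window(self):
        """Noiseless grand-average ratio tracks (1 - attenuation)."""
        comps = [ComponentSpec("P300", 320.0, 55.0, 8.0, gaussian_topography("Pz"),
                               conditions=("FDev", "DDev"))]
        effect = EffectSpec(attenuation={"P300": 0.5})
        coh = generate_cohort(
            6, 6, effect=effect, components=comps,
            noise=NoiseParams.none(), seed=3, gain_sd=0.05,
        )
        ctrl = np.concatenate(
            [s.epochs["FDev"] for s in coh.subjects if s.group == "control"]
        )
        conc = np.concatenate(
            [s.epochs["FDev"] for s in coh.subjects if s.group == "concussed"]
        )
        ratio = _p300_window_mean(conc) / _p300_window_mean(ctrl)
        assert ratio == pytest.approx(0.5, abs=0.08)

    def test_null_effect_groups_match_in_expectation(self):
        """With a null effect the group grand averages coincide within
        Monte-Carlo error of the between-subject variability."""
        coh = generate_cohort(
            8, 8, effect=EffectSpec.null(),
            noise=NoiseParams(pink_scale=1.0, alpha_scale=0.5, white_scale=0.5),
            seed=5,
        )
        ctrl = [
            _p300_window_mean(s.epochs["FDev"]) for s in coh.subjects if s.group == "control"
        ]
        conc = [
            _p300_window_mean(s.epochs["FDev"]) for s in coh.subjects if s.group == "concussed"
        ]
        diff = np.mean(conc) - np.mean(ctrl)
        se = np.sqrt(np.var(ctrl, ddof=1) / len(ctrl) + np.var(conc, ddof=1) / len(conc))
        assert abs(diff) < 3 * se

    def test_effect_monotonicity_noiseless(self):
        """Group difference in the P300 window grows with attenuation."""
        comps = [ComponentSpec("P300", 320.0, 55.0, 8.0, gaussian_topography("Pz"),
                               conditions=("FDev",))]
        diffs = []
        for att in (0.0, 0.25, 0.5, 0.75, 1.0):
            coh = generate_cohort(
                3, 3, effect=EffectSpec(attenuation={"P300": att}),
                components=comps, noise=NoiseParams.none(), seed=11, gain_sd=0.05,
            )
            ctrl = np.concatenate(
                [s.epochs["FDev"] for s in coh.subjects if s.group == "control"]
            )
            conc = np.concatenate(
                [s.epochs["FDev"] for s in coh.subjects if s.group == "concussed"]
            )
            diffs.append(_p300_window_mean(ctrl) - _p300_window_mean(conc))
        assert np.all(np.diff(diffs) > 0)

    def test_null_effect_label_permutation_is_exchangeable(self):
        """Label permutation test on P300-window means is non-significant
        in at least 90% of replicate null cohorts."""
        rng = np.random.default_rng(0)
        n_rep, n_sig = 40, 0
        for rep in range(n_rep):
            coh = generate_cohort(
                4, 4, effect=EffectSpec.null(),
                noise=NoiseParams(pink_scale=1.5, alpha_scale=1.0, white_scale=1.0),
                seed=1000 + rep, max_standard_epochs=4,
            )
            vals = np.array([_p300_window_mean(s.epochs["FDev"]) for s in coh.subjects])
            labels = np.array([s.group == "concussed" for s in coh.subjects])
            obs = abs(vals[labels].mean() - vals[~labels].mean())
            perm = np.array([
                abs(vals[p].mean() - vals[~p].mean())
                for p in (rng.permutation(labels) for _ in range(199))
            ])
            p_val = (1 + (perm >= obs).sum()) / 200
            n_sig += p_val <= 0.05
        assert n_sig / n_rep <= 0.10


class TestEffectSpecValidation:
    def test_attenuation_bounds(self):
        with pytest.raises(ValueError):
            EffectSpec(attenuation={"P300": 1.5})

    def test_topography_must_be_nonzero(self):
        with pytest.raises(ValueError, match="nonzero"):
            ComponentSpec("x", 100.0, 10.0, 1.0, np.zeros(64))

    def test_width_must_be_positive(self):
        with pytest.raises(ValueError, match="width"):
            ComponentSpec("x", 100.0, 0.0, 1.0, gaussian_topography("Cz"))
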