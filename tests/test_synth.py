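import numpy as np
import pytest
from scipy import signal as sps

from eegfatigue import (SimulationConfig, generate_questionnaire,
                        generate_session, inject_artifacts, synth_continuous)
from eegfatigue.montage import make_montage
from eegfatigue.synth import (QUESTIONNAIRE_ITEMS, Oscillator, alpha_profile,
                              stage_fatigue)
from conftest import SMALL_CONFIG


def test_generation_is_deterministic_per_seed():
    a = generate_session(SMALL_CONFIG, "mi")
    b = generate_session(SMALL_CONFIG, "mi")
    assert np.array_equal(a.eeg.signal, b.eeg.signal)
    assert a.segments == b.segments
    import dataclasses
    c = generate_session(dataclasses.replace(SMALL_CONFIG, seed=99), "mi")
    assert not np.array_equal(a.eeg.signal, c.eeg.signal)


def test_schedule_is_contiguous_and_complete(small_session):
    segs = small_session.segments
    cfg = small_session.config
    assert segs[0].onset == 0.0
    for prev, nxt in zip(segs, segs[1:]):
        assert nxt.onset == pytest.approx(prev.end, abs=1e-9)
    kinds = [s.kind for s in segs]
    assert kinds[:2] == ["pre-EC", "pre-EO"]
    assert kinds[-2:] == ["post-EC", "post-EO"]
    assert len(small_session.trials) == cfg.block_count * cfg.trials_per_block
    # every trial is rest -> mi -> pause with protocol durations
    for tr in small_session.trials:
        assert tr.mi_duration <= cfg.mi_max_s + 1e-9
        assert cfg.pause_range_s[0] - 1e-9 <= tr.pause_duration <= cfg.pause_range_s[1] + 1e-9
        if tr.success:
            assert tr.mi_duration >= cfg.mi_success_min_s - 1e-9
    rests = [s for s in segs if s.kind.endswith("-rest")]
    assert all(s.duration == pytest.approx(cfg.rest_trial_s) for s in rests)


def test_fatigue_truth_ramps_to_one_with_recovery_drops(small_session):
    f = small_session.fatigue_truth
    rate = small_session.eeg.rate
    assert f.min() >= 0.0
    vr = [s for s in small_session.segments if s.kind.startswith("block")]
    end_vr = int(round(vr[-1].end * rate)) - 1
    assert f[end_vr] == pytest.approx(1.0)
    # zero before VR, held constant after
    assert f[0] == 0.0
    assert np.all(f[end_vr:] == f[end_vr])
    # a recovery drop at the start of block 2
    b2 = next(s for s in small_session.segments if s.kind == "block2-rest")
    i = int(round(b2.onset * rate))
    assert f[i + 1] < f[i - 2]


def test_alpha_is_posterior_and_stronger_with_eyes_closed(small_session):
    eeg = small_session.eeg
    rate = eeg.rate
    m = small_session.montage
    o1 = m.index("O1")

    def band_power(seg, ch):
        i0, i1 = int(seg.onset * rate), int(seg.end * rate)
        fr, p = sps.welch(eeg.signal[ch, i0:i1], fs=rate, nperseg=int(2 * rate))
        sel = (fr >= 9.0) & (fr <= 11.0)
        return p[sel].mean()

    ec = next(s for s in small_session.segments if s.kind == "pre-EC")
    eo = next(s for s in small_session.segments if s.kind == "pre-EO")
    assert band_power(ec, o1) > 2.0 * band_power(eo, o1)
    # posterior dominance: O1 alpha beats a frontal site
    assert band_power(ec, o1) > band_power(ec, m.index("Fp1"))


def test_synth_continuous_validates_inputs():
    with pytest.raises(ValueError):
        synth_continuous(0.5, SMALL_CONFIG, [], seed=0)
    bad = Oscillator(10.0, 2.0, 1.0, np.ones(3))
    with pytest.raises(ValueError):
        synth_continuous(4.0, SMALL_CONFIG, [bad], seed=0)
    with pytest.raises(ValueError):
        Oscillator(10.0, 2.0, -1.0, np.ones(32))


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(erd_depth=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(pause_range_s=(5.0, 2.0))
    with pytest.raises(ValueError):
        SimulationConfig(ec_eo_ratio=0.5)
    with pytest.raises(ValueError):
        SimulationConfig(block_count=4)  # only 3 control probabilities given


def test_artifact_injection_is_conservative(small_session):
    cfg = small_session.config
    dirty, events = inject_artifacts(small_session.eeg, cfg, seed=777)
    assert len(events) > 0
    rate = small_session.eeg.rate
    recon = small_session.eeg.signal.copy()
    for ev in events:
        i0 = int(round(ev.onset * rate))
        recon[ev.channels, i0:i0 + ev.waveform.shape[1]] += ev.waveform
    assert np.array_equal(recon, dirty.signal)
    kinds = {ev.kind for ev in events}
    assert kinds <= {"blink", "emg"}


def test_control_condition_uses_sham_outcomes():
    rec = generate_session(SMALL_CONFIG, "control")
    assert all(tr.erd_attained == 0.0 for tr in rec.trials)
    with pytest.raises(ValueError):
        generate_session(SMALL_CONFIG, "sham")


def test_questionnaire_links_and_bounds(small_session):
    truth = stage_fatigue(small_session)
    assert truth.size == small_session.config.block_count + 2
    assert truth[0] == 0.0 and truth[-1] == pytest.approx(1.0)
    q = generate_questionnaire(truth, seed=5)
    assert q.responses.shape == (truth.size, len(QUESTIONNAIRE_ITEMS))
    assert q.responses.min() >= 1 and q.responses.max() <= 7
    # noiseless links are monotone in the planted fatigue
    q0 = generate_questionnaire(np.linspace(0, 1, 5), seed=0, noise_sd=0.0)
    mf = q0.item("mental_fatigue").astype(float)
    mot = q0.item("motivation").astype(float)
    assert np.all(np.diff(mf) >= 0) and mf[-1] > mf[0]
    assert np.all(np.diff(mot) <= 0) and mot[-1] < mot[0]


def test_mu_erd_suppresses_central_rhythm_during_imagery():
    cfg = SimulationConfig(sampling_rate=125.0, block_count=1, trials_per_block=6,
                           pre_post_rest_s=30.0, alpha_amplitude=0.0,
                           noise_rms=0.5, erd_depth=0.8, seed=3)
    rec = generate_session(cfg, "mi")
    rate = rec.eeg.rate
    c3 = rec.montage.index("C3")
    deep = [tr for tr in rec.trials if tr.erd_attained >= 0.6 * cfg.erd_depth]
    assert deep, "expected at least one successful trial"

    def mu_power(t0, t1):
        fr, p = sps.welch(rec.eeg.signal[c3, int(t0 * rate):int(t1 * rate)],
                          fs=rate, nperseg=int(2 * rate))
        sel = (fr >= 9.75) & (fr <= 11.75)
        return p[sel].mean()

    drops = [mu_power(tr.mi_onset + 1, tr.mi_onset + tr.mi_duration - 1)
             / mu_power(tr.rest_onset + 1, tr.mi_onset - 1) for tr in deep]
    assert np.median(drops) < 0.6


def test_montage_matches_channel_labels(small_session):
    assert small_session.eeg.channel_labels == make_montage(32).labels
    prof = alpha_profile(small_session.montage)
    assert prof.max() == pytest.approx(1.0)
    # profile peaks posteriorly
    labels = small_session.montage.labels
    assert labels[int(np.argmax(prof))] in ("O1", "O2", "POz", "PO3", "PO4")
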