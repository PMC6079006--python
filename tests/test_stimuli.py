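"""Stream construction: tuning, transition structure, timing, audio, 2AFC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from freqtag import stimuli
from freqtag.stimuli import (
    STAT_SET,
    TEST_SET,
    TONE_NAMES,
    TritoneSet,
    build_2afc_test,
    empirical_tp_matrix,
    find_tritone_set,
    generate_hab_sequence,
    generate_rdm_sequence,
    generate_stat_sequence,
    render_audio,
    tone_frequencies,
    triple_transition_matrix,
)


class TestToneFrequencies:
    def test_reference_pitch_and_equal_temperament(self):
        f = tone_frequencies()
        assert f["A"] == pytest.approx(440.0)
        # one-octave chromatic scale anchored at A4: C4 = 440 * 2^(-9/12)
        assert f["C"] == pytest.approx(261.63, abs=0.01)
        assert f["B"] == pytest.approx(493.88, abs=0.01)
        vals = [f[n] for n in TONE_NAMES]
        assert vals == sorted(vals)
        ratios = np.diff(np.log2(vals))
        assert np.allclose(ratios, 1 / 12)

    def test_scale_invariance(self):
        f440 = tone_frequencies(440.0)
        f220 = tone_frequencies(220.0)
        for name in TONE_NAMES:
            assert f220[name] == pytest.approx(f440[name] / 2)

    def test_rejects_nonpositive_reference(self):
        with pytest.raises(ValueError):
            tone_frequencies(0.0)


class TestTimingGrid:
    def test_tag_rates_from_printed_parameters(self):
        g = stimuli.DEFAULT_GRID
        assert g.tritone_period == pytest.approx(0.545)
        assert round(g.tone_rate, 3) == 5.505
        assert round(g.tritone_rate, 3) == 1.835
        assert g.tritone_rate == pytest.approx(g.tone_rate / 3)

    def test_onsets_follow_grid(self):
        seq = generate_stat_sequence(3, seed=0)
        expected = [0.0, 0.175, 0.350, 0.545, 0.720, 0.895, 1.090, 1.265, 1.440]
        assert np.allclose(seq.onsets, expected)
        assert np.allclose(seq.trigger_onsets, [0.0, 0.545, 1.090])
        assert seq.duration == pytest.approx(3 * 0.545)


class TestTritoneSets:
    def test_printed_sets_are_admissible(self):
        for s in (STAT_SET, TEST_SET):
            flat = [t for tri in s.triples for t in tri]
            assert sorted(flat) == sorted(TONE_NAMES)
        assert not STAT_SET.shares_structure_with(TEST_SET)

    def test_rejects_bad_partition(self):
        with pytest.raises(ValueError):
            TritoneSet((("C", "C#", "D"),) * 4)

    def test_search_finds_disjoint_set(self):
        cand = find_tritone_set(rng=7, existing=STAT_SET)
        assert not cand.shares_structure_with(STAT_SET)
        assert not cand.bigrams & STAT_SET.bigrams


class TestStatSequence:
    def test_single_triple(self):
        seq = generate_stat_sequence(1, seed=0)
        assert tuple(seq.tokens) in STAT_SET.triples
        assert seq.n_tokens == 3

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            generate_stat_sequence(0)

    def test_no_immediate_triple_repetition(self):
        seq = generate_stat_sequence(500, seed=3)
        triples = [tuple(seq.tokens[i : i + 3]) for i in range(0, len(seq.tokens), 3)]
        assert all(a != b for a, b in zip(triples, triples[1:]))

    def test_within_triple_tp_is_one(self):
        m = empirical_tp_matrix(generate_stat_sequence(1000, seed=1))
        for a, b, c in STAT_SET.triples:
            assert m.prob(a, b) == 1.0
            assert m.prob(b, c) == 1.0

    def test_triple_transitions_near_one_third(self):
        tm = triple_transition_matrix(generate_stat_sequence(1000, seed=2))
        off = tm[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off - 1 / 3) < 0.05)
        assert np.all(np.diag(tm) == 0)

    def test_seed_reproducibility(self):
        a = generate_stat_sequence(100, seed=42)
        b = generate_stat_sequence(100, seed=42)
        assert a.tokens == b.tokens


class TestRdmSequence:
    def test_no_immediate_repetition_and_zero_diagonal(self):
        seq = generate_rdm_sequence(5000, seed=4)
        assert all(a != b for a, b in zip(seq.tokens, seq.tokens[1:]))
        m = empirical_tp_matrix(seq)
        assert np.all(np.diag(m.probs) == 0)

    def test_uniform_offdiagonal_transitions(self):
        m = empirical_tp_matrix(generate_rdm_sequence(100_000, seed=5))
        off = m.probs[~np.eye(12, dtype=bool)]
        assert np.all(np.abs(off - 1 / 11) < 0.01)

    def test_same_grid_as_stat(self):
        seq = generate_rdm_sequence(6, seed=0)
        assert seq.grid.blank_every_3 == pytest.approx(0.020)


class TestHabSequence:
    def test_repeat_fraction(self):
        seq = generate_hab_sequence(10_000, repeat_prob=0.3, seed=6)
        frac = len(seq.repeat_marks) / 10_000
        assert abs(frac - 0.30) < 0.02

    @pytest.mark.parametrize("p,expected", [(0.0, 0), (1.0, 50)])
    def test_degenerate_probabilities(self, p, expected):
        seq = generate_hab_sequence(50, repeat_prob=p, seed=0)
        assert len(seq.repeat_marks) == expected

    def test_rejects_bad_probability(self):
        with pytest.raises(ValueError):
            generate_hab_sequence(10, repeat_prob=1.5)

    def test_scale_structure(self):
        seq = generate_hab_sequence(3, repeat_prob=0.0, seed=0)
        assert seq.tokens[:12] == list(TONE_NAMES)
        assert seq.tokens[12:24] == list(TONE_NAMES[::-1])
        assert seq.grid.blank_every_3 == 0.0


class TestTPMatrix:
    def test_hand_sequence(self):
        seq = stimuli.TokenSequence(["C", "D", "C", "D"], stream_type="RDM")
        m = empirical_tp_matrix(seq)
        assert m.prob("C", "D") == 1.0
        assert m.prob("D", "C") == 1.0

    def test_rows_normalised(self):
        m = empirical_tp_matrix(generate_rdm_sequence(1000, seed=7))
        sums = m.probs.sum(axis=1)
        nonzero = m.counts.sum(axis=1) > 0
        assert np.allclose(sums[nonzero], 1.0)

    def test_rejects_too_short(self):
        with pytest.raises(ValueError):
            empirical_tp_matrix(stimuli.TokenSequence(["C"], stream_type="RDM"))

    @settings(max_examples=20, deadline=None)
    @given(st.integers(min_value=2, max_value=200), st.integers(0, 2**31 - 1))
    def test_rdm_invariants_hold_for_any_length(self, n, seed):
        seq = generate_rdm_sequence(n, seed=seed)
        assert all(a != b for a, b in zip(seq.tokens, seq.tokens[1:]))
        assert np.all(np.diff(seq.onsets) > 0)


class TestRenderAudio:
    def test_duration_and_silences(self):
        seq = generate_stat_sequence(4, seed=0)
        fs = 16_000
        wav = render_audio(seq, sample_rate=fs)
        assert len(wav) == round(4 * 0.545 * fs)
        # blank after each triple is silent
        blank0 = wav[int(0.525 * fs) + 10 : int(0.545 * fs) - 10]
        assert np.all(blank0 == 0)

    def test_single_tone_envelope(self):
        seq = stimuli.TokenSequence(["A"], stream_type="RDM")
        fs = 48_000
        wav = render_audio(seq, sample_rate=fs, amplitude=1.0)
        tone = wav[: int(0.150 * fs)]
        assert np.max(np.abs(tone)) == pytest.approx(1.0, abs=0.01)
        assert np.max(np.abs(tone[: int(0.001 * fs)])) < 0.2  # ramped onset

    def test_rejects_sub_nyquist_rate(self):
        seq = generate_stat_sequence(1, seed=0)
        with pytest.raises(ValueError):
            render_audio(seq, sample_rate=800)

    def test_byte_identical_wav_under_seed(self, tmp_path):
        for name in ("a.wav", "b.wav"):
            seq = generate_stat_sequence(5, seed=11)
            stimuli.write_wav(tmp_path / name, render_audio(seq, sample_rate=16_000), 16_000)
        assert (tmp_path / "a.wav").read_bytes() == (tmp_path / "b.wav").read_bytes()


class TestAFC:
    def test_pairings_and_counterbalancing(self):
        afc = build_2afc_test(seed=0)
        assert len(afc.trials) == 16
        assert int(np.sum(afc.order_flags)) == 8
        assert len(set(afc.trials)) == 16  # every STAT x TEST combination once
        from collections import Counter

        counts = Counter()
        for s, t in afc.trials:
            counts[s] += 1
            counts[t] += 1
        assert all(v == 4 for v in counts.values())

    def test_two_seeds_same_pairings_different_order(self):
        a = build_2afc_test(seed=1)
        b = build_2afc_test(seed=2)
        assert sorted(a.trials) == sorted(b.trials)
        assert a.trials != b.trials

    def test_rejects_malformed_sets(self):
        bad = TritoneSet(STAT_SET.triples, label="STAT")
        object.__setattr__(bad, "triples", bad.triples[:2])
        with pytest.raises(ValueError):
            build_2afc_test(bad, TEST_SET)


def test_events_frame_roundtrip(tmp_path):
    seq = generate_stat_sequence(4, seed=0)
    path = tmp_path / "events.tsv"
    seq.to_tsv(path)
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    assert list(df.columns) == ["onset_s", "token", "triplet_id", "trigger_flag"]
    assert df["trigger_flag"].sum() == 4
    assert df["token"].tolist() == seq.tokens
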