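"""Corpus layer: MIDI round-trips, tokenization, synthetic generation."""

import numpy as np
import pytest
from scipy import stats

from songlearn.corpus import (
    SymbolSequence,
    SyntheticCorpusSpec,
    build_alphabet,
    corpus_manifest,
    detokenize,
    generate_synthetic_corpus,
    parse_token,
    quantize_duration,
    read_midi,
    tokenize,
    write_midi,
)
from songlearn.midi import (
    MidiFormatError,
    NoteEvent,
    read_midi_file,
    to_monophonic,
    write_midi_file,
)


class TestMidiIO:
    def test_single_note_round_trip(self, tmp_path):
        path = tmp_path / "one.mid"
        write_midi_file(path, [NoteEvent(onset=0.0, pitch=60, duration=1.0, velocity=90)])
        notes, tempo = read_midi_file(path)
        assert notes == [NoteEvent(onset=0.0, pitch=60, duration=1.0, velocity=90)]
        assert tempo == pytest.approx(120.0)

    def test_sequence_round_trip_preserves_tokens(self, tmp_path, motif_corpus):
        _, songs, _ = motif_corpus
        for song in songs[:3]:
            path = tmp_path / f"{song.source_id}.mid"
            write_midi(song, path)
            assert read_midi(path).tokens == song.tokens

    def test_simultaneous_notes_keep_highest_pitch(self, tmp_path):
        path = tmp_path / "chord.mid"
        write_midi_file(
            path,
            [
                NoteEvent(onset=0.0, pitch=60, duration=1.0),
                NoteEvent(onset=0.0, pitch=64, duration=1.0),
            ],
        )
        notes, _ = read_midi_file(path)
        assert [n.pitch for n in notes] == [64]

    def test_overlap_truncates_lower_voice(self):
        line = to_monophonic(
            [
                NoteEvent(onset=0.0, pitch=60, duration=2.0),
                NoteEvent(onset=1.0, pitch=67, duration=1.0),
            ]
        )
        assert [(n.pitch, n.onset, n.duration) for n in line] == [
            (60, 0.0, 1.0),
            (67, 1.0, 1.0),
        ]

    def test_corrupt_file_raises(self, tmp_path):
        bad = tmp_path / "bad.mid"
        bad.write_bytes(b"not a midi file at all")
        with pytest.raises(MidiFormatError):
            read_midi_file(bad)

    def test_empty_file_raises(self, tmp_path):
        path = tmp_path / "empty.mid"
        write_midi_file(path, [])
        with pytest.raises(MidiFormatError, match="no notes"):
            read_midi_file(path)


class TestTokenize:
    def test_distinct_pitches_distinct_tokens(self):
        events = [
            NoteEvent(onset=0.0, pitch=60, duration=1.0),
            NoteEvent(onset=1.0, pitch=62, duration=1.0),
        ]
        seq = tokenize(events)
        assert len(set(seq.tokens)) == 2

    def test_duration_is_part_of_the_symbol(self):
        events = [
            NoteEvent(onset=0.0, pitch=60, duration=1.0),
            NoteEvent(onset=1.0, pitch=60, duration=2.0),
        ]
        assert len(set(tokenize(events).tokens)) == 2

    def test_detokenize_round_trip(self, motif_corpus):
        _, songs, _ = motif_corpus
        seq = songs[0]
        assert tokenize(detokenize(seq), source_id=seq.source_id).tokens == seq.tokens

    def test_out_of_grid_duration_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert quantize_duration(9.0) == 4.0
        with pytest.warns(UserWarning):
            assert quantize_duration(0.05) == 0.25

    def test_token_codec(self):
        assert parse_token("p60d1.5") == (60, 1.5)

    def test_empty_events_rejected(self):
        with pytest.raises(ValueError):
            tokenize([])


class TestSyntheticCorpus:
    def test_degenerate_rate_one_tiles_motif(self):
        spec = SyntheticCorpusSpec(
            n_songs=5, alphabet_size=3, motifs=((0, 1, 2),), motif_rate=1.0,
            song_length=9, seed=0,
        )
        songs, motifs = generate_synthetic_corpus(spec)
        (motif,) = motifs
        for song in songs:
            assert tuple(song.tokens) == motif * 3

    def test_rate_zero_is_uniform(self):
        spec = SyntheticCorpusSpec(
            n_songs=100, alphabet_size=8, motifs=((0, 1),), motif_rate=0.0,
            song_length=100, seed=3,
        )
        songs, _ = generate_synthetic_corpus(spec)
        tokens = [t for s in songs for t in s.tokens]
        counts = np.bincount(
            [build_alphabet(8).index(t) for t in tokens], minlength=8
        )
        assert stats.chisquare(counts).pvalue > 1e-3

    def test_fixed_seed_is_reproducible(self):
        spec = SyntheticCorpusSpec(seed=7)
        a, _ = generate_synthetic_corpus(spec)
        b, _ = generate_synthetic_corpus(spec)
        assert [s.tokens for s in a] == [s.tokens for s in b]

    def test_motif_frequency_bound(self):
        """Planted motifs appear at least 80% as often as the emission rate implies."""
        spec = SyntheticCorpusSpec(seed=2)  # 50 songs x 60 tokens, rate 0.5
        songs, (motif,) = generate_synthetic_corpus(spec)
        pattern = "|".join(motif)
        hits = sum("|".join(s.tokens).count(pattern) for s in songs)
        # per emission step: p=0.5 motif (3 tokens) else 1 token -> 2 tokens/step
        steps = sum(len(s) for s in songs) / 2.0
        assert hits >= 0.8 * 0.5 * steps

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            SyntheticCorpusSpec(motifs=((0, 1, 2, 3, 4),))
        with pytest.raises(ValueError):
            SyntheticCorpusSpec(alphabet_size=2, motifs=((0, 5),))
        with pytest.raises(ValueError):
            SyntheticCorpusSpec(motif_rate=1.5)
        with pytest.raises(ValueError):
            SyntheticCorpusSpec(motifs=((0, 1),), motif_weights=(1.0, 2.0))

    def test_manifest_columns(self, motif_corpus):
        _, songs, _ = motif_corpus
        table = corpus_manifest(songs, culture="test")
        assert list(table.columns) == ["song_id", "path", "n_tokens", "culture"]
        assert (table["n_tokens"] == 60).all()


def test_symbol_sequence_must_be_nonempty():
    with pytest.raises(ValueError):
        SymbolSequence(tokens=[])
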