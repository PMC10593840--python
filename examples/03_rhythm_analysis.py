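"""Measure the amplitude-modulation rhythm of a generated song.

Renders a generated melody to audio, z-normalizes it, infers the AM
envelope (modulator) by MAP amplitude demodulation, and reports the mean
scalogram power in the slow 1-3 Hz band versus the 3-5 Hz band.
"""

import numpy as np

from songlearn import composer
from songlearn.corpus import SyntheticCorpusSpec, generate_synthetic_corpus
from songlearn.learning import ExperimentConfig, run_learning
from songlearn.rhythm import band_powers, pad_demodulate, scalogram, synthesize, znorm

# long motif notes (1 beat) against short noise notes (1/2 beat)
spec = SyntheticCorpusSpec(
    seed=1, durations=[1.0, 1.0, 1.0] + [0.5] * 9,
)
corpus, _ = generate_synthetic_corpus(spec)
snapshots, _ = run_learning(corpus, ExperimentConfig(n_trials=15, seed=1))

song = composer.generate_song(snapshots[-1], 60, seed=7)
audio = znorm(synthesize(song))  # 16 kHz sine voice at 120 BPM
demod = pad_demodulate(audio)
print(f"audio: {audio.duration:.1f} s; envelope reconstruction residual "
      f"{demod.residual:.1e}")

spec_ = scalogram(demod.modulator, audio.rate)
b13, b35 = band_powers(spec_)
peak = spec_.frequencies[np.argmax(spec_.mean_power)]
print(f"scalogram peak {peak:.2f} Hz; band power 1-3 Hz = {b13:.2f}, "
      f"3-5 Hz = {b35:.2f}")
print("1-beat notes at 120 BPM arrive at 2 Hz, so a motif-dominated song")
print("concentrates envelope power in the slow 1-3 Hz (delta) band.")
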