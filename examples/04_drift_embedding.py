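"""Track how generated music drifts away from the training corpus.

For each of the 15 learning-amount models, generates 20 songs, averages
their note-bigram distributions, and measures the Jensen-Shannon distance
from the corpus distribution; then embeds all 16 distributions in 2-D with
t-SNE and reports how the distance from the "original" point grows with
learning.
"""

import numpy as np
from scipy import stats

from songlearn import analytics, composer
from songlearn.corpus import SyntheticCorpusSpec, generate_synthetic_corpus
from songlearn.learning import ExperimentConfig, run_learning

corpus, _ = generate_synthetic_corpus(SyntheticCorpusSpec(seed=0))
snapshots, _ = run_learning(corpus, ExperimentConfig(n_trials=15, seed=0))
original = analytics.average_generated_distribution(corpus, label="original")

vecs = []
for k, model in enumerate(snapshots, start=1):
    songs = composer.generate_set(model, 20, 60, seed=100 + k)
    vecs.append(analytics.average_generated_distribution(songs, label=f"trial-{k}"))

traj = analytics.distance_trajectory(vecs, original)
rho = stats.spearmanr(range(1, 16), traj)[0]
for k, d in enumerate(traj, start=1):
    print(f"trial {k:2d}: JS distance from corpus = {d:.3f}")
print(f"\nSpearman(trial, distance) = {rho:+.2f} — deeper hierarchies "
      "recombine units and push the output away from the original songs.")

emb = analytics.tsne_embed([original, *vecs], seed=0)
d = np.linalg.norm(emb[1:] - emb[0], axis=1)
print("t-SNE rank correlation of embedded distance with trial: "
      f"{stats.spearmanr(range(1, 16), d)[0]:+.2f}")
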