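"""t-SNE views of raw spectra vs learned hidden-layer features.

Embeds the raw absorbance matrix and each encoder layer's activations in
2-D and prints a simple class-separation score for each representation
(mean between-class centroid distance over mean within-class spread).
Writes a 3-panel scatter figure when matplotlib is importable.
"""

import numpy as np

from ftirsel import (
    SyntheticConfig,
    TrainOptions,
    generate,
    scale_to_unit_interval,
    tsne_embed,
)
from ftirsel.ssae import fit_ssae


def separation(coords, y):
    cents = np.stack([coords[y == c].mean(0) for c in np.unique(y)])
    between = np.mean(
        [np.linalg.norm(a - b) for i, a in enumerate(cents) for b in cents[i + 1:]]
    )
    within = np.mean(
        [np.linalg.norm(coords[y == c] - cents[c], axis=1).mean()
         for c in np.unique(y)]
    )
    return between / within


cfg = SyntheticConfig(n_points=600, n_per_class=30, seed=0)
dataset, _ = generate(cfg)
scaled, _ = scale_to_unit_interval(dataset)
model = fit_ssae(
    scaled.absorbance, dataset.labels, (64, 13),
    pretrain_opts=TrainOptions(epochs=150, learning_rate=0.2, seed=0),
    finetune_opts=TrainOptions(epochs=1000, learning_rate=0.1, momentum=0.95, seed=0),
)
acts = model.activations(scaled.absorbance)

views = {
    "raw spectra": dataset.absorbance,
    "hidden layer 1": acts[0],
    "hidden layer 2": acts[1],
}
coords = {}
for name, F in views.items():
    coords[name] = tsne_embed(F, seed=0)
    print(f"{name:15s} separation score {separation(coords[name], dataset.labels):.2f}")
print("-> deeper representations should separate the classes more cleanly")

try:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    for ax, (name, c) in zip(axes, coords.items()):
        ax.scatter(c[:, 0], c[:, 1], c=dataset.labels, cmap="tab20", s=12)
        ax.set_title(name)
    fig.tight_layout()
    fig.savefig("tsne_views.png", dpi=120)
    print("scatter panels written to tsne_views.png")
except ImportError:
    print("matplotlib not available; skipped the figure")
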