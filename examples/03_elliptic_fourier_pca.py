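"""Elliptic Fourier shape analysis: chain code -> coefficients -> PCA.

Traces each silhouette into a Freeman chain, expands it into 20 elliptic
Fourier harmonics, normalizes by the first-harmonic ellipse (so size,
rotation, translation and start point drop out), and summarizes the shape
variation with a principal component analysis.
"""

import numpy as np

from berrymorph import efd, synth

configs = [
    synth.VarietyConfig("Round", "sphere", 25.0, 0.8, 24.5, 0.8, 24.5, 0.8, n_berries=8),
    synth.VarietyConfig("Long", "ellipse", 33.0, 1.2, 21.0, 0.9, 21.5, 0.9, n_berries=8),
    synth.VarietyConfig("Teardrop", "drop", 30.0, 1.0, 22.0, 0.9, 22.5, 0.9,
                        asym=0.3, n_berries=8),
]
masks, _ = synth.generate_dataset(configs, master_seed=21, scale=0.1)
ids, efds = efd.analyze_masks(masks, n_harmonics=20, orientation="horizontal")

first = efds[0]
print("normalized first harmonic (a1, b1, c1, d1):", first.coeffs[0].round(4))
print("-> a1 = 1, b1 = c1 = 0 by construction; d1 is the aspect ratio of "
      "the first-harmonic ellipse\n")

pca = efd.fit_pca(efd.efd_matrix(efds))
print("variance explained:",
      ", ".join(f"PC{i + 1} {100 * p:.2f}%" for i, p in enumerate(pca.proportions[:3])))

scores = ids.copy()
scores["PC1"] = pca.scores[:, 0]
scores["PC2"] = pca.scores[:, 1]
print("\nmean PC scores per variety:")
print(scores.groupby("variety")[["PC1", "PC2"]].mean().round(4).to_string())
print("\nPC1 orders outlines by elongation (round < teardrop ~ long); the "
      "drop family separates on a later component via its even harmonics.")

# visualize what PC1 encodes: outline at mean -2 SD vs mean vs mean +2 SD
for k in (-2.0, 0.0, 2.0):
    poly = efd.pc_shape(pca, 0, k)
    aspect = (poly[:, 0].max() - poly[:, 0].min()) / (poly[:, 1].max() - poly[:, 1].min())
    print(f"PC1 at {k:+.0f} SD: bounding-box aspect ratio {aspect:.3f}")
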