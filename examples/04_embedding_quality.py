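"""Train the graph attention autoencoder and inspect the embedding.

Shows that the 32-dim latent embedding separates the true tissue layers
better than the raw normalized expression, measured by silhouette width.
"""

from sklearn.metrics import silhouette_score

from adept import SimConfig, filter_genes, generate_layered_dataset, normalize
from adept.gae import GAEConfig, train_gae
from adept.graph import build_knn_graph

dataset, truth = generate_layered_dataset(SimConfig(seed=5))
norm = normalize(filter_genes(dataset, 5))
graph = build_knn_graph(dataset.coords, k=6)

cfg = GAEConfig(layer_dims=[norm.n_genes, 128, 32], iterations=200, seed=0)
params, emb = train_gae(norm.values, graph, cfg)

print(f"reconstruction loss: {emb.loss_history[0]:.4f} -> {emb.loss_history[-1]:.4f}")
print(f"silhouette vs true layers, raw matrix:  "
      f"{silhouette_score(norm.values, truth.labels):.3f}")
print(f"silhouette vs true layers, embedding:   "
      f"{silhouette_score(emb.H, truth.labels):.3f}")
print("a higher silhouette means spots of the same layer sit closer together "
      "relative to other layers; spatial attention pulls neighbors into "
      "agreement.")
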