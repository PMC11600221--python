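"""Leave-one-class-out and leave-one-product-out categorization.

Sugar task: hold out each extreme concentration class (2.5 / 10 %w/w of
glucose and sucrose) in turn, relabel the middle 5% level toward the
held-out side and predict type+level for the unseen class — pooling 40 test
predictions. Milk task: hold out each of 12 commercial products and predict
its protein source from sibling products of the same source.
"""

import gafsense as gs

sugar = gs.generate_task_dataset("sugar", gs.SimulationConfig(seed=1))
rep = gs.sugar_locov_eval(sugar, head="LDA", k_components=20, seed=1)
print(f"sugar type+level: pooled accuracy {rep.pooled_accuracy:.1%} "
      f"over {rep.n_pooled} held-out predictions (classes: {rep.class_names})")

milk = gs.generate_task_dataset("milk", gs.SimulationConfig(seed=1))
rep = gs.milk_lopo_eval(milk, head="LDA", k_components=20, seed=1)
print(f"milk source: pooled accuracy {rep.pooled_accuracy:.1%} "
      f"over {rep.n_pooled} predictions from {len(rep.accuracies)} held-out products")

# unsupervised check: do the four beverage categories separate at all?
bev = gs.generate_task_dataset("clustering", gs.SimulationConfig(seed=1))
fset = gs.featurize_dataset(bev)
scores = gs.transform_pca(gs.fit_pca(fset, 5), fset)
ari, _ = gs.cluster_and_score(scores, n_clusters=4)
print(f"ward/Euclidean clustering of {fset.n} beverages into 4 groups: ARI = {ari:.3f} "
      "(1 = clusters match the true categories)")
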