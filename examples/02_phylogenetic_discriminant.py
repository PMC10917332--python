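"""Phylogenetic LDA on synthetic data with a known answer.

Builds a small two-class compactness dataset on a simulated tree, runs the
discriminant across an ensemble of branch-length-randomized trees, and
summarizes the posterior probability of diver-class membership for a test
taxon placed at the diver-class centroid (which should be classified with
near certainty) — one posterior per tree, as in the workflow under audit.
"""

import numpy as np

from pfda_audit import fit_pfda, pure_birth_tree, random_ensemble
from pfda_audit.datasets import ClassPartition, ClassRule, TaxonRecord

rng = np.random.default_rng(4)
n = 15
terr = [TaxonRecord(f"terr_{i}", float(np.exp(rng.normal(2.5, 0.4))),
                    float(np.clip(rng.normal(0.55, 0.08), 0.01, 1)), "0", "0")
        for i in range(n)]
divers = [TaxonRecord(f"diver_{i}", float(np.exp(rng.normal(2.8, 0.4))),
                      float(np.clip(rng.normal(0.85, 0.08), 0.01, 1)), "0", "2")
          for i in range(n)]
part = ClassPartition(terr, divers, ClassRule("F0D0_vs_F0D2"))

tree = pure_birth_tree(2 * n + 1, seed=5)
leaves = list(tree.leaf_node_iter())
for leaf, rec in zip(leaves, part.records):
    leaf.taxon.label = rec.taxon_id
leaves[-1].taxon.label = "probe"

test = [TaxonRecord("probe", float(np.exp(2.8)), 0.85, "0", "unknown", role="test")]
ensemble = random_ensemble(tree, n=100, seed=6)
summaries, per_tree = fit_pfda(part, ensemble, test, lam=0.05)

s = summaries[0]
lo, hi = s.ci95
A = np.median([m.A for m in per_tree])
print(f"training accuracy (median over {len(ensemble)} trees): {A:.3f}")
print(f"probe at the diver centroid: median P2 = {s.median_p2:.3f}, "
      f"95% spread ({lo:.3f}, {hi:.3f}), classified as diver in "
      f"{s.classified_d2_count}/100 trees")
print("-> with well-separated synthetic classes the posterior is decisive; "
      "on real compactness data it rarely is")
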