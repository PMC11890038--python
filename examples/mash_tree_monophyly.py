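"""The presence/absence route: MinHash sketches, Mash distances, NJ trees.

Sketches every simulated genome (bottom-s hashes of its filtered canonical
k-mer set), estimates pairwise Jaccard indices from merged sketches,
converts them to Mash distances d = -(1/k) ln(2j/(1+j)), builds a
neighbor-joining tree, and asks whether each population is monophyletic —
over a small (k, sketch size) grid, as one would scan parameters on real
data.
"""

import tempfile

import kmerpop as kp

config = kp.scenario_library("three-pop", scale=0.01, seed=0)
samples = kp.simulate(config)

with tempfile.TemporaryDirectory() as tmp:
    manifest = kp.write_fasta(samples, tmp)
    grid = kp.monophyly_sweep(manifest, ks=[9, 11], ss=[200, 1000, 5000])
print(grid.to_string(index=False))
print()
print("A True cell means every population forms a clade on that NJ tree.")
print("Accuracy depends on (k, s) jointly: small sketches can miss a group that")
print("a larger sketch resolves. And k must be >= 9 at this genome size: every")
print("canonical 7-mer is present in every sample, so presence alone carries no")
print("signal there (frequencies still do).")

# a single tree, written as newick
from kmerpop.sketchdist import distance_matrix, nj_tree, sketch, tree_to_newick

params = kp.SketchParams(k=9, s=1000)
sketches = [sketch(r.sequence, params, r.sample_id) for r in samples.records]
tree = nj_tree(distance_matrix(sketches))
print("\nNJ tree (k=9, s=1000):")
print(tree_to_newick(tree))
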