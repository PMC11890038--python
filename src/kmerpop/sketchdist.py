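"""MinHash sketching, Mash distances, neighbor-joining and monophyly.

The presence/absence comparison route: each genome's filtered canonical
k-mer set is reduced to a bottom-s MinHash sketch (the s smallest values of
a stable seeded 64-bit hash over the k-mers), pairwise Jaccard indices are
estimated from merged sketches, converted to Mash distances
``d = -(1/k) * ln(2j / (1 + j))``, and the resulting distance matrix is
summarised as an unrooted neighbor-joining tree.  Whether each labeled
group of samples is monophyletic on that tree — over a grid of (k, sketch
size) parameters — measures how well k-mer presence alone recovers the
grouping.

The hash is a keyed blake2b digest truncated to 64 bits; sketches built
with different (k, s, min_count, hash_seed) parameters are never
comparable.  A Jaccard of zero maps to the saturation distance 1.0.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import TreeNode, nj

from .kmerprof import KmerParams, count_kmers, read_fasta, read_manifest

__all__ = [
    "SketchParams",
    "Sketch",
    "DistanceMatrix",
    "sketch",
    "sketch_from_fasta",
    "jaccard",
    "mash_distance",
    "distance_matrix",
    "nj_tree",
    "tree_to_newick",
    "is_monophyletic",
    "monophyly_sweep",
    "write_sketch_json",
    "read_sketch_json",
]


@dataclass(frozen=True)
class SketchParams:
    """k-mer length, sketch size, count filter and hash seed."""

    k: int
    s: int
    min_count: int = 2
    hash_seed: int = 42

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.s < 1:
            raise ValueError(f"sketch size must be >= 1, got {self.s}")
        if self.min_count < 1:
            raise ValueError(f"min_count must be >= 1, got {self.min_count}")


@dataclass
class Sketch:
    """Bottom-s sketch: sorted distinct 64-bit hashes of retained k-mers."""

    params: SketchParams
    hashes: list[int]
    sample_id: str = "sample"

    def __len__(self) -> int:
        return len(self.hashes)


def _hash_kmer(kmer: str, seed: int) -> int:
    digest = hashlib.blake2b(
        kmer.encode("ascii"), digest_size=8, key=seed.to_bytes(8, "little")
    ).digest()
    return int.from_bytes(digest, "big")


def sketch(
    sequences: str | Iterable[str], params: SketchParams, sample_id: str = "sample"
) -> Sketch:
    """Bottom-s MinHash sketch of a sample's filtered canonical k-mer set."""
    profile = count_kmers(
        sequences, KmerParams(params.k, params.min_count), sample_id=sample_id
    )
    if not profile.counts:
        warnings.warn(f"sample {sample_id!r}: no k-mers survive filtering; empty sketch")
        return Sketch(params, [], sample_id)
    hashes = sorted(_hash_kmer(km, params.hash_seed) for km in profile.counts)
    return Sketch(params, hashes[: params.s], sample_id)


def sketch_from_fasta(path: str | Path, params: SketchParams, sample_id: str | None = None) -> Sketch:
    records = read_fasta(path)
    sid = sample_id if sample_id is not None else Path(path).stem
    return sketch((seq for _, seq in records), params, sample_id=sid)


def jaccard(a: Sketch, b: Sketch) -> float:
    """Mash-style Jaccard estimate from two bottom-s sketches.

    The s smallest hashes of the merged sets form the union sketch; the
    returned estimate is the fraction of union-sketch hashes present in
    both inputs.
    """
    if a.params != b.params:
        raise ValueError(f"sketch parameter mismatch: {a.params} vs {b.params}")
    sa, sb = set(a.hashes), set(b.hashes)
    union = sorted(sa | sb)[: a.params.s]
    if not union:
        warnings.warn("both sketches empty; Jaccard undefined, returning 0")
        return 0.0
    shared = sum(1 for h in union if h in sa and h in sb)
    return shared / len(union)


def mash_distance(j: float, k: int) -> float:
    """Mutation-rate-like distance from a Jaccard index.

    ``d = -(1/k) * ln(2j / (1+j))``; the zero-overlap case saturates at
    1.0 by convention, and identical k-mer sets give 0.
    """
    if not 0.0 <= j <= 1.0:
        raise ValueError(f"Jaccard index must be in [0, 1], got {j}")
    if j == 0.0:
        return 1.0
    return max(0.0, -math.log(2.0 * j / (1.0 + j)) / k)


@dataclass
class DistanceMatrix:
    names: list[str]
    d: np.ndarray  # symmetric, zero diagonal

    def to_skbio(self) -> _SkbioDM:
        return _SkbioDM(self.d, ids=self.names)


def distance_matrix(sketches: Sequence[Sketch]) -> DistanceMatrix:
    """All pairwise Mash distances among sketches sharing parameters."""
    if len(sketches) < 3:
        raise ValueError("need at least 3 sketches")
    params = sketches[0].params
    if any(s.params != params for s in sketches):
        raise ValueError("all sketches must share parameters")
    n = len(sketches)
    d = np.zeros((n, n))
    for i in range(n):
        for jx in range(i + 1, n):
            dist = mash_distance(jaccard(sketches[i], sketches[jx]), params.k)
            d[i, jx] = d[jx, i] = dist
    return DistanceMatrix([s.sample_id for s in sketches], d)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; negative branch lengths clamped to 0.

    Returns an unrooted tree (represented with a basal trifurcation).
    """
    if len(dm.names) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.allclose(dm.d, dm.d.T):
        raise ValueError("distance matrix is not symmetric")
    return nj(dm.to_skbio(), neg_as_zero=True)


def tree_to_newick(tree: TreeNode) -> str:
    s = str(tree).strip()
    return s if s.endswith(";") else s + ";"


def _bipartitions(tree: TreeNode) -> list[frozenset[str]]:
    """Leaf set under each non-root edge of the (unrooted) tree."""
    parts = []
    for node in tree.traverse(include_self=False):
        parts.append(frozenset(leaf.name for leaf in node.tips(include_self=True)))
    return parts


def is_monophyletic(tree: TreeNode, leaves: Iterable[str]) -> bool:
    """True iff some edge splits the leaf set exactly into (leaves, rest).

    Evaluated on the unrooted tree, so a group equal to the complement of a
    clade also counts.  Singletons and the full leaf set are trivially
    monophyletic.
    """
    group = frozenset(leaves)
    if not group:
        raise ValueError("empty leaf group")
    all_leaves = frozenset(leaf.name for leaf in tree.tips())
    unknown = group - all_leaves
    if unknown:
        raise ValueError(f"labels not in tree: {sorted(unknown)}")
    if len(group) <= 1 or group == all_leaves:
        return True
    complement = all_leaves - group
    for part in _bipartitions(tree):
        if part == group or part == complement:
            return True
    return False


def monophyly_sweep(
    manifest,
    ks: Sequence[int],
    ss: Sequence[int],
    min_count: int = 2,
    hash_seed: int = 42,
) -> pd.DataFrame:
    """Monophyly of every label group over a (k, sketch size) grid.

    For each (k, s) all samples are sketched, an NJ tree is built from
    pairwise Mash distances, and each label group is tested for monophyly.
    Returns a tidy frame with one row per (k, s): per-label boolean columns
    plus ``all_monophyletic``, ready for a heatmap.
    """
    df = manifest if isinstance(manifest, pd.DataFrame) else read_manifest(manifest)
    if "label" not in df.columns:
        raise ValueError("monophyly sweep requires a manifest with a label column")
    groups: dict[str, list[str]] = {}
    for row in df.itertuples():
        groups.setdefault(row.label, []).append(row.sample_id)
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValueError("need >= 2 labels with >= 2 samples each")
    sequences = {
        row.sample_id: [seq for _, seq in read_fasta(row.path)] for row in df.itertuples()
    }
    rows = []
    for k in ks:
        for s in ss:
            params = SketchParams(k=k, s=s, min_count=min_count, hash_seed=hash_seed)
            sketches = [
                sketch(sequences[sid], params, sample_id=sid) for sid in df["sample_id"]
            ]
            tree = nj_tree(distance_matrix(sketches))
            result = {
                label: is_monophyletic(tree, members) for label, members in groups.items()
            }
            rows.append(
                {"k": k, "s": s, **result, "all_monophyletic": all(result.values())}
            )
    return pd.DataFrame(rows)


def write_sketch_json(sk: Sketch, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "sample_id": sk.sample_id,
                "k": sk.params.k,
                "s": sk.params.s,
                "min_count": sk.params.min_count,
                "hash_seed": sk.params.hash_seed,
                "hashes": sk.hashes,
            },
            fh,
        )


def read_sketch_json(path: str | Path) -> Sketch:
    with open(path) as fh:
        obj = json.load(fh)
    params = SketchParams(obj["k"], obj["s"], obj["min_count"], obj["hash_seed"])
    return Sketch(params, list(obj["hashes"]), obj["sample_id"])
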