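"""Canonical k-mer profiles: counting, filtering, spectra, shared features.

Builds a toy sequence and a small random genome, counts canonical k-mers
(strand-independent: each window is represented by the lexicographic
minimum of itself and its reverse complement), filters singletons, and
shows how the frequency spectrum guides the choice of k.
"""

import numpy as np

import kmerpop as kp

# toy example: every window of ACGTACGT, canonicalized
profile = kp.count_kmers("ACGTACGT", kp.KmerParams(k=4, min_count=1))
print("4-mer profile of ACGTACGT:", profile.counts)
print("  (5 windows; GTAC occurs once, so min_count=2 would drop it)")

filtered = kp.count_kmers("ACGTACGT", kp.KmerParams(k=4, min_count=2))
print("singleton-filtered profile:", filtered.counts)

# a 100 kb random genome: the count spectrum tells us which k is informative
rng = np.random.default_rng(0)
genome = "".join(rng.choice(list("ACGT"), size=100_000))
for k in (7, 9, 11):
    prof = kp.count_kmers(genome, kp.KmerParams(k, min_count=2))
    spectrum = kp.frequency_spectrum(prof)
    mean_count = np.mean(list(prof.counts.values()))
    print(f"k={k:2d}: {len(prof):6d} distinct k-mers kept, mean count {mean_count:.1f}")
best = kp.kmerprof.select_k(genome, candidates=(7, 9, 11))
print(f"spectrum-symmetry rule selects k={best} for this genome size")
print("  (larger k saturates at the count filter; smaller k saturates the k-mer space)")

# shared features across two related samples = the PCA feature space
other = list(genome)
for pos in rng.integers(0, len(other), 50):  # 50 point mutations
    other[pos] = "ACGT"[(("ACGT".index(other[pos])) + 1) % 4]
prof_a = kp.count_kmers(genome, kp.KmerParams(9, 2), sample_id="a")
prof_b = kp.count_kmers("".join(other), kp.KmerParams(9, 2), sample_id="b")
shared = kp.shared_kmers([prof_a, prof_b])
matrix = kp.build_matrix([prof_a, prof_b], shared)
print(f"shared 9-mers after filtering: {len(shared)} -> count matrix {matrix.counts.shape}")
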