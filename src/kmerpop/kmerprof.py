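"""Canonical k-mer frequency profiles of genomes.

A genome is summarised as a map from canonical k-mer (the lexicographically
smaller of a k-mer and its reverse complement) to its count over all sliding
windows of the sequence.  Counting is strand-independent by construction.
Low-count k-mers (singletons by default) are filtered out as likely
sequencing artifacts, and a set of samples is reduced to the exact
intersection of their filtered k-mer sets, yielding an integer count matrix
(samples x shared k-mers) suitable for downstream ordination.

Counting is exact and hash-map based; k is capped at 31 so every k-mer fits
a 2-bit-packed 64-bit integer, which is how the vectorised counter works
internally.  Windows containing any non-ACGT symbol (e.g. N) are skipped,
not errors: consensus FASTA files routinely contain them.  Lowercase
(soft-masked) input is uppercased before counting.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "KmerParams",
    "KmerProfile",
    "KmerMatrix",
    "reverse_complement",
    "canonical",
    "count_kmers",
    "frequency_spectrum",
    "shared_kmers",
    "build_matrix",
    "read_fasta",
    "profile_from_fasta",
    "read_manifest",
    "matrix_from_manifest",
    "write_profile_tsv",
    "read_profile_tsv",
    "write_matrix_tsv",
]

MAX_K = 31

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# base -> 2-bit code; the code order A=0 < C=1 < G=2 < T=3 matches lexicographic
# order, so comparing packed integers compares k-mer strings.
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class KmerParams:
    """k-mer length and the minimum per-sample count for retention.

    ``min_count=2`` drops singletons, the default filtering rule for
    consensus genomes where k-mers of frequency one are dominated by errors.
    """

    k: int
    min_count: int = 2

    def __post_init__(self) -> None:
        if not 1 <= self.k <= MAX_K:
            raise ValueError(f"k must be in [1, {MAX_K}], got {self.k}")
        if self.min_count < 1:
            raise ValueError(f"min_count must be >= 1, got {self.min_count}")


@dataclass
class KmerProfile:
    """Filtered canonical k-mer counts of one sample."""

    sample_id: str
    k: int
    counts: dict[str, int]
    min_count: int = 1

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class KmerMatrix:
    """Samples x shared-k-mers integer count matrix (intersection features)."""

    sample_ids: list[str]
    features: list[str]
    counts: np.ndarray  # (n_samples, n_features) int64

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.features)


def _validate_dna(seq: str) -> None:
    for pos, ch in enumerate(seq):
        if ch not in "ACGTacgt":
            raise ValueError(f"non-ACGT character {ch!r} at position {pos}")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string; raises on non-ACGT characters."""
    _validate_dna(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """The lexicographically smaller of a k-mer and its reverse complement."""
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def _window_codes(seq: str, k: int) -> np.ndarray:
    """Packed canonical codes of every valid k-window of one sequence."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = _CODE[arr]
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    invalid = (codes < 0).astype(np.int64)
    csum = np.concatenate(([0], np.cumsum(invalid)))
    bad_in_window = csum[k:] - csum[:-k]  # length n
    c = np.where(codes < 0, 0, codes).astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    three = np.uint64(3)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | c[j : j + n]
        rev |= (three - c[j : j + n]) << np.uint64(2 * j)
    canon = np.minimum(fwd, rev)
    return canon[bad_in_window == 0]


def _decode_codes(codes: np.ndarray, k: int) -> list[str]:
    if codes.size == 0:
        return []
    shifts = np.arange(2 * (k - 1), -1, -2, dtype=np.uint64)
    idx = (codes[:, None] >> shifts) & np.uint64(3)
    chars = _BASES[idx.astype(np.intp)]
    return [s.decode("ascii") for s in np.ascontiguousarray(chars).view(f"S{k}").ravel()]


def count_kmers(
    sequences: str | Iterable[str],
    params: KmerParams,
    sample_id: str = "sample",
) -> KmerProfile:
    """Count canonical k-mers over one or more sequences of a sample.

    Records of a multi-sequence sample (e.g. chromosomes) are pooled into a
    single profile.  Windows containing non-ACGT symbols are skipped.  After
    counting, entries below ``params.min_count`` are removed.  An input with
    no valid window yields an empty profile with a warning.
    """
    if isinstance(sequences, str):
        sequences = [sequences]
    parts = [_window_codes(seq, params.k) for seq in sequences]
    allcodes = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint64)
    if allcodes.size == 0:
        warnings.warn(f"sample {sample_id!r}: no valid {params.k}-mer window; empty profile")
        return KmerProfile(sample_id, params.k, {}, params.min_count)
    uniq, cnt = np.unique(allcodes, return_counts=True)
    keep = cnt >= params.min_count
    uniq, cnt = uniq[keep], cnt[keep]
    if uniq.size == 0:
        warnings.warn(
            f"sample {sample_id!r}: no k-mer reached min_count={params.min_count}; empty profile"
        )
    counts = dict(zip(_decode_codes(uniq, params.k), (int(c) for c in cnt)))
    return KmerProfile(sample_id, params.k, counts, params.min_count)


def frequency_spectrum(profile: KmerProfile) -> dict[int, int]:
    """Histogram count -> number of distinct k-mers with that count.

    Useful for choosing k: a roughly symmetric spectrum indicates a k-mer
    space neither saturated (k too small) nor dominated by unique k-mers
    (k too large) for the genome at hand.
    """
    spectrum: dict[int, int] = {}
    for c in profile.counts.values():
        spectrum[c] = spectrum.get(c, 0) + 1
    return spectrum


def select_k(
    sequences: str | Iterable[str],
    candidates: Sequence[int] = (7, 9, 11, 13, 15, 17, 19, 21),
    min_count: int = 2,
) -> int:
    """Choose k by frequency-spectrum symmetry.

    For each candidate k the filtered count spectrum of the input is
    computed and its sample skewness measured; the k whose spectrum is
    closest to symmetric (smallest |skewness|) is returned.  A strongly
    right-skewed spectrum means most k-mers sit at the filter boundary
    (k too large for the genome size); a left-skewed or saturated one
    means k is too small to be informative.
    """
    if isinstance(sequences, str):
        sequences = [sequences]
    seqs = list(sequences)
    best_k, best_skew = None, np.inf
    for k in candidates:
        profile = count_kmers(seqs, KmerParams(k, min_count))
        if not profile.counts:
            continue
        vals = np.fromiter(profile.counts.values(), dtype=float)
        sd = vals.std()
        skew = abs(((vals - vals.mean()) ** 3).mean() / sd**3) if sd > 0 else np.inf
        if skew < best_skew:
            best_k, best_skew = k, skew
    if best_k is None:
        raise ValueError("no candidate k yields a non-empty filtered profile")
    return best_k


def shared_kmers(profiles: Sequence[KmerProfile]) -> list[str]:
    """Exact intersection of the profiles' k-mer sets, sorted ascending."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to intersect")
    ks = {p.k for p in profiles}
    if len(ks) != 1:
        raise ValueError(f"profiles have mixed k: {sorted(ks)}")
    common = set(profiles[0].counts)
    for p in profiles[1:]:
        common &= p.counts.keys()
    if not common:
        warnings.warn("empty k-mer intersection across samples")
    return sorted(common)


def build_matrix(profiles: Sequence[KmerProfile], features: Sequence[str]) -> KmerMatrix:
    """Assemble the samples x features count matrix over shared features."""
    counts = np.empty((len(profiles), len(features)), dtype=np.int64)
    for i, p in enumerate(profiles):
        for j, f in enumerate(features):
            try:
                counts[i, j] = p.counts[f]
            except KeyError:
                raise KeyError(f"k-mer {f!r} missing from sample {p.sample_id!r}") from None
    return KmerMatrix([p.sample_id for p in profiles], list(features), counts)


# ---------------------------------------------------------------------------
# IO: FASTA (plain or gzip), manifest TSV, profile/matrix TSV


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """All (record id, sequence) pairs of a plain or gzipped FASTA file."""
    with _open_text(path) as fh:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]


def profile_from_fasta(
    path: str | Path, params: KmerParams, sample_id: str | None = None
) -> KmerProfile:
    """Pooled profile of all records of one FASTA file (one sample)."""
    if sample_id is None:
        name = Path(path).name
        for ext in (".gz", ".fasta", ".fa", ".fna"):
            if name.endswith(ext):
                name = name[: -len(ext)]
        sample_id = name
    records = read_fasta(path)
    return count_kmers((seq for _, seq in records), params, sample_id=sample_id)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Manifest TSV with columns sample_id, path, label (label optional).

    Relative paths are resolved against the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"sample_id", "path"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks required column(s): {sorted(missing)}")
    df["path"] = [
        str(p if Path(p).is_absolute() else path.parent / p) for p in df["path"]
    ]
    return df


def matrix_from_manifest(
    manifest: str | Path | pd.DataFrame, params: KmerParams
) -> tuple[KmerMatrix, list[str] | None]:
    """Profiles for every manifest row, intersected into a KmerMatrix.

    Returns the matrix and, if the manifest has a label column, the labels
    in row order.
    """
    df = manifest if isinstance(manifest, pd.DataFrame) else read_manifest(manifest)
    profiles = [
        profile_from_fasta(row.path, params, sample_id=row.sample_id)
        for row in df.itertuples()
    ]
    features = shared_kmers(profiles)
    matrix = build_matrix(profiles, features)
    labels = list(df["label"]) if "label" in df.columns else None
    return matrix, labels


def write_profile_tsv(profile: KmerProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("kmer\tcount\n")
        for kmer in sorted(profile.counts):
            fh.write(f"{kmer}\t{profile.counts[kmer]}\n")


def read_profile_tsv(path: str | Path, sample_id: str | None = None) -> KmerProfile:
    df = pd.read_csv(path, sep="\t", dtype={"kmer": str, "count": int})
    counts = dict(zip(df["kmer"], (int(c) for c in df["count"])))
    k = len(next(iter(counts))) if counts else 0
    return KmerProfile(sample_id or Path(path).stem, k, counts)


def write_matrix_tsv(matrix: KmerMatrix, path: str | Path) -> None:
    matrix.to_frame().rename_axis("sample_id").to_csv(path, sep="\t")
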