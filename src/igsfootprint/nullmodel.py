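"""Shuffled-alignment null model for conserved k-mer statistics.

Shuffling destroys positional homology while preserving exactly what the
conservation statistic must be compared against: each row's base composition
and the alignment's gap architecture.  Two modes are provided:

``row_residue_permutation`` (default)
    each row's non-gap characters are permuted uniformly among that row's
    non-gap positions; gaps stay fixed.  Per-row composition is exactly
    preserved and all cross-row identity structure is destroyed.

``column_permutation``
    whole columns are permuted uniformly among columns sharing the same gap
    pattern.  Column-level identity is preserved; only contiguity is broken.
    Useful as a sensitivity check on the contribution of run structure.

Random streams are derived from (seed, replicate_index, igs_index) so every
replicate is reproducible independently of iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .align import GAP, MultipleAlignment
from .conservation import find_conserved_kmers

MODES = ("row_residue_permutation", "column_permutation")


@dataclass
class ShuffleConfig:
    mode: str = "row_residue_permutation"
    replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown shuffle mode {self.mode!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class NullDistribution:
    config: ShuffleConfig
    histogram_mean: dict[int, float]      # k -> mean count per replicate
    histogram_sd: dict[int, float]
    igs_with_kmer_counts: list[int]       # one entry per replicate
    replicate_histograms: list[dict[int, int]] = field(default_factory=list)

    @property
    def mean_igs_with_kmer(self) -> float:
        return float(np.mean(self.igs_with_kmer_counts))


def _rng(seed: int, replicate_index: int, igs_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(replicate_index, igs_index))
    )


def shuffle_alignment(
    aln: MultipleAlignment,
    config: ShuffleConfig,
    replicate_index: int = 0,
    igs_index: int = 0,
) -> MultipleAlignment:
    """One shuffled replicate of an alignment (deterministic per indices)."""
    rng = _rng(config.seed, replicate_index, igs_index)
    arr = aln.as_array().copy()
    gap = ord(GAP)
    if config.mode == "row_residue_permutation":
        for i in range(arr.shape[0]):
            nz = np.flatnonzero(arr[i] != gap)
            arr[i, nz] = arr[i, nz[rng.permutation(len(nz))]]
    else:
        gap_patterns = (arr == gap).T  # columns x rows
        keys = [tuple(col) for col in gap_patterns]
        groups: dict[tuple, list[int]] = {}
        for j, key in enumerate(keys):
            groups.setdefault(key, []).append(j)
        perm = np.arange(arr.shape[1])
        for cols in groups.values():
            cols = np.asarray(cols)
            perm[cols] = cols[rng.permutation(len(cols))]
        arr = arr[:, perm]
    rows = [bytes(arr[i]).decode() for i in range(arr.shape[0])]
    return MultipleAlignment(
        source_key=aln.source_key,
        taxa=list(aln.taxa),
        rows=rows,
        engine_tag=f"{aln.engine_tag}+shuffle:{config.mode}",
    )


def null_kmer_distribution(
    alignments: Mapping[tuple, MultipleAlignment] | Sequence[MultipleAlignment],
    config: ShuffleConfig,
    min_k: int = 5,
    taxa_subsets: Mapping[tuple, Sequence[str]] | None = None,
) -> NullDistribution:
    """Rerun the k-mer scan on shuffled replicates of every alignment.

    Aggregates the null length histogram (mean and sd of per-k counts over
    replicates) and, per replicate, the number of spacers that retain at
    least one conserved k-mer by chance.
    """
    if isinstance(alignments, Mapping):
        items = list(alignments.items())
    else:
        items = [(getattr(a, "source_key", i), a) for i, a in enumerate(alignments)]
    per_rep_hist: list[dict[int, int]] = []
    igs_counts: list[int] = []
    for rep in range(config.replicates):
        hist: dict[int, int] = {}
        n_with = 0
        for idx, (key, aln) in enumerate(items):
            shuffled = shuffle_alignment(aln, config, rep, idx)
            subset = taxa_subsets.get(key) if taxa_subsets else None
            kms = find_conserved_kmers(shuffled, subset, min_k=min_k)
            if kms:
                n_with += 1
            for km in kms:
                hist[km.k] = hist.get(km.k, 0) + 1
        per_rep_hist.append(hist)
        igs_counts.append(n_with)
    all_k = sorted({k for h in per_rep_hist for k in h})
    mean = {
        k: float(np.mean([h.get(k, 0) for h in per_rep_hist])) for k in all_k
    }
    sd = {
        k: float(np.std([h.get(k, 0) for h in per_rep_hist], ddof=1))
        if config.replicates > 1
        else 0.0
        for k in all_k
    }
    return NullDistribution(
        config=config,
        histogram_mean=mean,
        histogram_sd=sd,
        igs_with_kmer_counts=igs_counts,
        replicate_histograms=per_rep_hist,
    )


def write_null_histogram(null: NullDistribution, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("k\tmean_count\tsd\n")
        for k in sorted(null.histogram_mean):
            fh.write(f"{k}\t{null.histogram_mean[k]:.3f}\t{null.histogram_sd[k]:.3f}\n")
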