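"""Perfectly conserved k-mers in multiple alignments, and derived statistics.

A conserved k-mer is a maximal run of >= min_k consecutive alignment columns
that are gap-free and identical across a chosen taxon set.  At divergences
where neutral sites are saturated, such runs are strong evidence of purifying
selection, which is the footprinting logic: count them, compare against a
shuffled-alignment null, and group nearby runs into blocks that behave as
single putative functional elements.

Only maximal runs are counted; sub-windows of a run are not reported, so
coverage fractions and length histograms partition alignment columns cleanly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .align import GAP, MultipleAlignment


@dataclass(frozen=True)
class ConservedKmer:
    source_key: str
    start_col: int
    k: int
    sequence: str
    conserved_taxa: frozenset
    gc_fraction: float
    at_only: bool

    @property
    def end_col(self) -> int:
        return self.start_col + self.k


@dataclass
class KmerBlock:
    members: list[ConservedKmer]
    qualifying_rule: str  # pair_within_30 | single_ge_10

    @property
    def span(self) -> tuple[int, int]:
        return (self.members[0].start_col, self.members[-1].end_col)


def conserved_column_mask(
    aln: MultipleAlignment, taxa_subset: Sequence[str] | None = None
) -> np.ndarray:
    """Boolean mask of columns gap-free and identical across the subset."""
    taxa = list(taxa_subset) if taxa_subset is not None else list(aln.taxa)
    if len(taxa) < 2:
        raise ValueError("taxa subset must contain at least two taxa")
    unknown = set(taxa) - set(aln.taxa)
    if unknown:
        raise ValueError(f"taxa not in alignment: {sorted(unknown)}")
    arr = aln.as_array()
    idx = [aln.taxa.index(t) for t in taxa]
    sub = arr[idx]
    gap = ord(GAP)
    mask = np.all(sub == sub[0], axis=0) & (sub[0] != gap)
    return mask


def find_conserved_kmers(
    aln: MultipleAlignment,
    taxa_subset: Sequence[str] | None = None,
    min_k: int = 5,
) -> list[ConservedKmer]:
    """All maximal conserved runs of >= min_k columns, sorted by start."""
    taxa = list(taxa_subset) if taxa_subset is not None else list(aln.taxa)
    mask = conserved_column_mask(aln, taxa)
    row = aln.row(taxa[0])
    out = []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    tset = frozenset(taxa)
    for s, e in zip(starts, ends):
        k = int(e - s)
        if k < min_k:
            continue
        seq = row[s:e]
        gc = (seq.count("G") + seq.count("C")) / k
        out.append(
            ConservedKmer(
                source_key=aln.source_key,
                start_col=int(s),
                k=k,
                sequence=seq,
                conserved_taxa=tset,
                gc_fraction=gc,
                at_only=gc == 0.0,
            )
        )
    return out


def nested_kmer_partition(
    aln: MultipleAlignment,
    nested_subsets: Sequence[Sequence[str]],
    min_k: int = 5,
) -> dict[frozenset, list[ConservedKmer]]:
    """Assign each conserved region to the deepest taxon set conserving it.

    ``nested_subsets`` is ordered deepest first (largest taxon set down to
    the smallest) and must be strictly nested.  Each maximal run of the
    shallowest (smallest) subset is assigned once, to the deepest subset in
    which at least ``min_k`` of its columns remain perfectly conserved; the
    shallower lists therefore hold only the *additional* regions not seen at
    any greater depth, and the depth lists partition the shallowest scan.
    """
    sets = [frozenset(s) for s in nested_subsets]
    for deep, shallow in zip(sets, sets[1:]):
        if not (shallow < deep):
            raise ValueError("subsets must be strictly nested, deepest first")
    masks = {s: conserved_column_mask(aln, sorted(s)) for s in sets}
    shallow_kmers = find_conserved_kmers(aln, sorted(sets[-1]), min_k=min_k)
    out: dict[frozenset, list[ConservedKmer]] = {s: [] for s in sets}
    for km in shallow_kmers:
        assigned = sets[-1]
        for s in sets:  # deepest first
            window = masks[s][km.start_col : km.end_col]
            run = _longest_true_run(window)
            if run >= min_k:
                assigned = s
                break
        out[assigned].append(km)
    return out


def _longest_true_run(mask: np.ndarray) -> int:
    best = cur = 0
    for v in mask:
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return best


def group_into_blocks(
    kmers: Sequence[ConservedKmer], max_gap: int = 30, single_min: int = 10
) -> list[KmerBlock]:
    """Chain nearby k-mers into blocks (the putative-element unit).

    Consecutive k-mers whose separation (next start minus previous end, in
    alignment columns) is strictly less than ``max_gap`` chain transitively
    into one block; an unchained k-mer forms a block on its own only if
    k >= ``single_min``.
    """
    kms = sorted(kmers, key=lambda k: k.start_col)
    blocks: list[list[ConservedKmer]] = []
    for km in kms:
        if blocks and km.start_col - blocks[-1][-1].end_col < max_gap:
            blocks[-1].append(km)
        else:
            blocks.append([km])
    out = []
    for members in blocks:
        if len(members) >= 2:
            out.append(KmerBlock(members=members, qualifying_rule="pair_within_30"))
        elif members[0].k >= single_min:
            out.append(KmerBlock(members=members, qualifying_rule="single_ge_10"))
    return out


def conservation_summary(
    alignments: Mapping[tuple, MultipleAlignment],
    kmers_by_key: Mapping[tuple, Sequence[ConservedKmer]],
    categories: Mapping[tuple, str] | None = None,
    coverage_min_k: int = 6,
) -> dict:
    """Aggregate conservation statistics across spacer alignments.

    Returns per-spacer counts, per-orientation-category k-mer densities
    (k-mers per 100 alignment columns), the coverage fraction by k-mers of
    k >= ``coverage_min_k``, AT-only counts, and the k length histogram.
    """
    from .align import mean_identity

    per_igs = {}
    histogram: dict[int, int] = {}
    cat_data: dict[str, dict] = {}
    total_cols = 0
    covered_cols = 0
    n_at_only = 0
    n_kmers = 0
    for key, aln in alignments.items():
        kms = list(kmers_by_key.get(key, ()))
        cov = sum(k.k for k in kms if k.k >= coverage_min_k)
        label = "|".join(key) if isinstance(key, tuple) else str(key)
        per_igs[label] = {
            "kmer_count": len(kms),
            "block_count": len(group_into_blocks(kms)),
            "covered_columns": cov,
            "alignment_length": aln.n_columns,
        }
        total_cols += aln.n_columns
        covered_cols += cov
        n_kmers += len(kms)
        for k in kms:
            histogram[k.k] = histogram.get(k.k, 0) + 1
            if k.at_only:
                n_at_only += 1
        cat = categories.get(key, "all") if categories else "all"
        d = cat_data.setdefault(
            cat, {"kmers": 0, "columns": 0, "identities": [], "n_igs": 0}
        )
        d["kmers"] += len(kms)
        d["columns"] += aln.n_columns
        d["n_igs"] += 1
        try:
            d["identities"].append(mean_identity(aln))
        except Exception:
            pass
    per_category = {}
    for cat, d in cat_data.items():
        per_category[cat] = {
            "n_igs": d["n_igs"],
            "kmer_density_per_100nt": 100.0 * d["kmers"] / d["columns"]
            if d["columns"]
            else 0.0,
            "mean_alignment_length": d["columns"] / d["n_igs"],
            "mean_identity": float(np.mean(d["identities"]))
            if d["identities"]
            else float("nan"),
        }
    assert sum(histogram.values()) == n_kmers
    return {
        "per_igs": per_igs,
        "per_category": per_category,
        "histogram": dict(sorted(histogram.items())),
        "n_kmers": n_kmers,
        "n_at_only": n_at_only,
        "n_igs_with_kmer": sum(1 for v in per_igs.values() if v["kmer_count"] > 0),
        "coverage_columns": covered_cols,
        "total_columns": total_cols,
        "coverage_fraction": covered_cols / total_cols if total_cols else 0.0,
    }


# ---------------------------------------------------------------------------
# spacer length correlations


@dataclass
class CorrelationResult:
    taxon_pair: tuple[str, str]
    n: int
    r: float
    fisher_z: float

    def __post_init__(self) -> None:
        assert -1.0 <= self.r <= 1.0


class UndefinedCorrelation(ValueError):
    pass


def length_correlation(
    lengths_a: Sequence[float], lengths_b: Sequence[float], taxon_pair=("a", "b")
) -> CorrelationResult:
    """Pearson correlation of paired raw spacer lengths, with Fisher z."""
    x = np.asarray(lengths_a, dtype=float)
    y = np.asarray(lengths_b, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need >= 4 paired lengths")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelation("zero variance in a length vector")
    r = float(stats.pearsonr(x, y).statistic)
    r = max(-1.0, min(1.0, r))
    z = float(np.arctanh(r)) if abs(r) < 1 else float("inf") * np.sign(r)
    return CorrelationResult(tuple(taxon_pair), len(x), r, z)


def compare_correlations(
    r1: float, n1: int, r2: float, n2: int
) -> tuple[float, float]:
    """Fisher r-to-z comparison of two independent Pearson correlations.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)); two-sided p
    from the standard normal.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("Fisher r-to-z needs n > 3 in both samples")
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise UndefinedCorrelation("|r| = 1: z is infinite (boundary result)")
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (np.arctanh(r1) - np.arctanh(r2)) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def write_kmer_table(kmers: Sequence[ConservedKmer], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("igs_key\tstart_col\tk\tsequence\ttaxa\tgc_fraction\tat_only\n")
        for km in kmers:
            fh.write(
                f"{km.source_key}\t{km.start_col}\t{km.k}\t{km.sequence}\t"
                f"{','.join(sorted(km.conserved_taxa))}\t{km.gc_fraction:.3f}\t"
                f"{int(km.at_only)}\n"
            )


def project_kmers_to_genome(
    aln: MultipleAlignment,
    kmers: Sequence[ConservedKmer],
    taxon: str,
    igs_start: int,
    contig_id: str,
) -> list[tuple[str, int, int, str]]:
    """Project k-mer alignment spans to genome coordinates (BED rows)."""
    posmap = aln.position_map(taxon)  # residue -> column
    col_to_pos = {int(c): i for i, c in enumerate(posmap)}
    rows = []
    for km in kmers:
        cols = [col_to_pos[c] for c in range(km.start_col, km.end_col) if c in col_to_pos]
        if not cols:
            continue
        rows.append(
            (contig_id, igs_start + min(cols), igs_start + max(cols) + 1, km.sequence)
        )
    return rows
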