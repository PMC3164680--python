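"""Progressive multiple alignment with affine gap costs.

The statistics downstream (conserved k-mer scans, identity, length
bookkeeping) are engine-agnostic: any aligner that returns equal-length
gapped rows can be plugged in via :func:`align_set`'s ``engine`` argument.
The built-in engine is a deterministic progressive aligner — global pairwise
profile-profile dynamic programming (Gotoh) merged along a guide tree — so
the whole pipeline runs hermetically.  DP traceback ties are broken
diagonal, then up (gap in the second profile), then left; this fixes the
output for given inputs and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

GAP = "-"


class AlignmentError(ValueError):
    pass


@dataclass
class AlignParams:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0


@dataclass
class MultipleAlignment:
    """Equal-length gapped rows over an ordered taxon list."""

    source_key: str
    taxa: list[str]
    rows: list[str]
    engine_tag: str = "builtin-progressive"
    _array: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise AlignmentError("an alignment needs at least two rows")
        if len(set(len(r) for r in self.rows)) != 1:
            raise AlignmentError("alignment rows differ in length")
        if len(self.taxa) != len(self.rows):
            raise AlignmentError("taxa/rows mismatch")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def ungapped(self, taxon: str) -> str:
        return self.row(taxon).replace(GAP, "")

    def as_array(self) -> np.ndarray:
        """Byte view (n_rows x n_columns) for vectorised column scans."""
        if self._array is None or self._array.shape[0] != len(self.rows):
            self._array = np.array(
                [np.frombuffer(r.encode(), dtype=np.uint8) for r in self.rows]
            )
        return self._array

    def column_of_position(self, taxon: str, pos: int) -> int:
        """Alignment column holding residue ``pos`` (0-based) of a taxon."""
        row = self.row(taxon)
        seen = -1
        for col, ch in enumerate(row):
            if ch != GAP:
                seen += 1
                if seen == pos:
                    return col
        raise IndexError(f"position {pos} beyond sequence of {taxon}")

    def position_map(self, taxon: str) -> np.ndarray:
        """Array mapping residue index -> alignment column for a taxon."""
        row = np.frombuffer(self.row(taxon).encode(), dtype=np.uint8)
        return np.flatnonzero(row != ord(GAP))


# ---------------------------------------------------------------------------
# pairwise / profile DP


def _col_score(acol: Sequence[str], bcol: Sequence[str], p: AlignParams) -> float:
    """Mean pairwise substitution score between two profile columns.

    Pairs where either residue is an (existing) gap contribute 0, so old gaps
    are neutral; new gaps are charged via the affine penalties.
    """
    total = 0.0
    n = 0
    for a in acol:
        for b in bcol:
            n += 1
            if a == GAP or b == GAP:
                continue
            total += p.match if a == b else p.mismatch
    return total / n


def align_profiles(
    prof_a: list[str], prof_b: list[str], params: AlignParams | None = None
) -> tuple[list[str], list[str]]:
    """Global affine-gap alignment of two gapped profiles (Gotoh).

    Returns the two profiles with new gap columns inserted so all rows share
    one coordinate system.
    """
    p = params or AlignParams()
    acols = ["".join(r[i] for r in prof_a) for i in range(len(prof_a[0]))] if prof_a[0] else []
    bcols = ["".join(r[i] for r in prof_b) for i in range(len(prof_b[0]))] if prof_b[0] else []
    n, m = len(acols), len(bcols)
    NEG = -1e30
    sub = np.empty((n, m))
    for i in range(n):
        ai = acols[i]
        for j in range(m):
            sub[i, j] = _col_score(ai, bcols[j], p)
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in B (consume A)
    Y = np.full((n + 1, m + 1), NEG)  # gap in A (consume B)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = p.gap_open + (i - 1) * p.gap_extend
    for j in range(1, m + 1):
        Y[0, j] = p.gap_open + (j - 1) * p.gap_extend
    # traceback pointers: 0 diag(M), 1 up(X), 2 left(Y); per matrix
    ptrM = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrX = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrY = np.zeros((n + 1, m + 1), dtype=np.int8)
    for i in range(1, n + 1):
        Mi1 = M[i - 1]
        Xi1 = X[i - 1]
        Yi1 = Y[i - 1]
        for j in range(1, m + 1):
            s = sub[i - 1, j - 1]
            best, arg = Mi1[j - 1], 0
            if Xi1[j - 1] > best:
                best, arg = Xi1[j - 1], 1
            if Yi1[j - 1] > best:
                best, arg = Yi1[j - 1], 2
            M[i, j] = best + s
            ptrM[i, j] = arg
            xo = Mi1[j] + p.gap_open
            xe = Xi1[j] + p.gap_extend
            if xo >= xe:
                X[i, j], ptrX[i, j] = xo, 0
            else:
                X[i, j], ptrX[i, j] = xe, 1
            yo = M[i, j - 1] + p.gap_open
            ye = Y[i, j - 1] + p.gap_extend
            if yo >= ye:
                Y[i, j], ptrY[i, j] = yo, 0
            else:
                Y[i, j], ptrY[i, j] = ye, 2
    i, j = n, m
    state = int(np.argmax([M[n, m], X[n, m], Y[n, m]]))  # diag preferred on tie
    ops: list[int] = []
    while i > 0 or j > 0:
        if i == 0:
            ops.append(2)
            j -= 1
            continue
        if j == 0:
            ops.append(1)
            i -= 1
            continue
        if state == 0:
            prev = ptrM[i, j]
            ops.append(0)
            i -= 1
            j -= 1
            state = prev
        elif state == 1:
            prev = ptrX[i, j]
            ops.append(1)
            i -= 1
            state = 0 if prev == 0 else 1
        else:
            prev = ptrY[i, j]
            ops.append(2)
            j -= 1
            state = 0 if prev == 0 else 2
    ops.reverse()
    gap_a = GAP * len(prof_a)
    gap_b = GAP * len(prof_b)
    new_a = [[] for _ in prof_a]
    new_b = [[] for _ in prof_b]
    ia = ib = 0
    for op in ops:
        if op in (0, 1):
            for k, r in enumerate(new_a):
                r.append(acols[ia][k])
            ia += 1
        else:
            for r in new_a:
                r.append(GAP)
        if op in (0, 2):
            for k, r in enumerate(new_b):
                r.append(bcols[ib][k])
            ib += 1
        else:
            for r in new_b:
                r.append(GAP)
    return ["".join(r) for r in new_a], ["".join(r) for r in new_b]


def pairwise_score(a: str, b: str, params: AlignParams | None = None) -> float:
    """Optimal global affine-gap alignment score of two sequences."""
    p = params or AlignParams()
    ra, rb = align_profiles([a], [b], p)
    return _alignment_score(ra[0], rb[0], p)


def _alignment_score(ra: str, rb: str, p: AlignParams) -> float:
    score = 0.0
    in_gap_a = in_gap_b = False
    for x, y in zip(ra, rb):
        if x == GAP:
            score += p.gap_extend if in_gap_a else p.gap_open
            in_gap_a, in_gap_b = True, False
        elif y == GAP:
            score += p.gap_extend if in_gap_b else p.gap_open
            in_gap_b, in_gap_a = True, False
        else:
            score += p.match if x == y else p.mismatch
            in_gap_a = in_gap_b = False
    return score


# ---------------------------------------------------------------------------
# progressive MSA


def _merge_order_from_tree(tree, taxa: set[str]) -> list:
    """Post-order list of (left_taxa, right_taxa) merges from a dendropy tree."""
    merges = []

    def walk(node) -> list[str]:
        if node.is_leaf():
            name = node.taxon.label if node.taxon else None
            if name not in taxa:
                raise AlignmentError(f"unknown taxon in guide tree: {name!r}")
            return [name]
        child_sets = [walk(c) for c in node.child_nodes()]
        child_sets = [c for c in child_sets if c]
        acc = child_sets[0]
        for nxt in child_sets[1:]:
            merges.append((list(acc), list(nxt)))
            acc = acc + nxt
        return acc

    covered = walk(tree.seed_node)
    missing = taxa - set(covered)
    for name in sorted(missing):
        merges.append((list(covered), [name]))
        covered = covered + [name]
    return merges


def _guide_merges_from_identity(
    seqs: Mapping[str, str], params: AlignParams
) -> list:
    """UPGMA-style merge order from pairwise alignment identities."""
    names = sorted(seqs)
    clusters: list[list[str]] = [[n] for n in names]
    ident: dict[tuple[str, str], float] = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            ra, rb = align_profiles([seqs[a]], [seqs[b]], params)
            same = sum(
                1 for x, y in zip(ra[0], rb[0]) if x == y and x != GAP
            )
            both = sum(1 for x, y in zip(ra[0], rb[0]) if x != GAP and y != GAP)
            ident[(a, b)] = ident[(b, a)] = same / both if both else 0.0
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean(
                    [ident[(a, b)] for a in clusters[i] for b in clusters[j]]
                )
                if best is None or d > best[0]:
                    best = (d, i, j)
        _, i, j = best
        merges.append((list(clusters[i]), list(clusters[j])))
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return merges


def align_set(
    seqs: Mapping[str, str],
    guide_tree=None,
    params: AlignParams | None = None,
    source_key: str = "",
    engine: Callable[..., MultipleAlignment] | None = None,
) -> MultipleAlignment:
    """Multiple alignment of a set of taxon-labelled sequences.

    ``guide_tree`` is a rooted dendropy tree whose leaf labels cover the
    taxa; without one, a merge order is derived from pairwise identities.
    ``engine`` replaces the built-in aligner entirely (external-tool
    adapter); it receives the same arguments and must return a
    :class:`MultipleAlignment`.
    """
    if engine is not None:
        return engine(seqs, guide_tree=guide_tree, params=params, source_key=source_key)
    if len(seqs) < 2:
        raise AlignmentError("need at least two sequences")
    for t, s in seqs.items():
        if not s:
            raise AlignmentError(f"empty sequence for taxon {t}")
    p = params or AlignParams()
    if guide_tree is not None:
        merges = _merge_order_from_tree(guide_tree, set(seqs))
    else:
        merges = _guide_merges_from_identity(seqs, p)
    profiles: dict[frozenset, tuple[list[str], list[str]]] = {
        frozenset([t]): ([t], [seqs[t].upper()]) for t in seqs
    }
    for left, right in merges:
        lk, rk = frozenset(left), frozenset(right)
        lt, lrows = profiles.pop(lk)
        rt, rrows = profiles.pop(rk)
        na, nb = align_profiles(lrows, rrows, p)
        profiles[lk | rk] = (lt + rt, na + nb)
    (taxa, rows), = profiles.values()
    order = sorted(range(len(taxa)), key=lambda i: taxa[i])
    aln = MultipleAlignment(
        source_key=source_key,
        taxa=[taxa[i] for i in order],
        rows=[rows[i] for i in order],
    )
    for taxon in seqs:
        assert aln.ungapped(taxon) == seqs[taxon].upper()
    return aln


# ---------------------------------------------------------------------------
# codon-aware CDS alignment

_STOPS = {"TAA", "TAG", "TGA"}


def align_cds_by_protein(
    cds: Mapping[str, str],
    guide_tree=None,
    params: AlignParams | None = None,
    source_key: str = "",
) -> MultipleAlignment:
    """Align coding sequences via their proteins, then back-translate.

    Gaps therefore fall on codon boundaries and every row's codons are
    preserved exactly.  Sequences must be intact genes: length divisible by
    three and no internal stop codon.
    """
    from Bio.Seq import Seq

    prots: dict[str, str] = {}
    for taxon, seq in cds.items():
        seq = seq.upper()
        if len(seq) % 3 != 0:
            raise AlignmentError(f"{taxon}: CDS length {len(seq)} not divisible by 3")
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        for idx, codon in enumerate(codons[:-1]):
            if codon in _STOPS:
                raise AlignmentError(f"{taxon}: internal stop codon at codon {idx}")
        body = codons[:-1] if codons[-1] in _STOPS else codons
        prots[taxon] = str(Seq("".join(body)).translate())
    paln = align_set(prots, guide_tree=guide_tree, params=params, source_key=source_key)
    rows = []
    for taxon in paln.taxa:
        seq = cds[taxon].upper()
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        has_stop = codons[-1] in _STOPS
        body = codons[:-1] if has_stop else codons
        out = []
        ci = 0
        for ch in paln.row(taxon):
            if ch == GAP:
                out.append(GAP * 3)
            else:
                out.append(body[ci])
                ci += 1
        if has_stop:
            out.append(codons[-1])
        rows.append("".join(out))
    if any(len(r) != len(rows[0]) for r in rows):
        # stop codons present in some rows only: pad
        width = max(len(r) for r in rows)
        rows = [r + GAP * (width - len(r)) for r in rows]
    return MultipleAlignment(
        source_key=source_key, taxa=list(paln.taxa), rows=rows,
        engine_tag="builtin-progressive/codon",
    )


def mean_identity(aln: MultipleAlignment) -> float:
    """Mean pairwise identity over columns where both rows are ungapped."""
    arr = aln.as_array()
    gap = ord(GAP)
    vals = []
    for i in range(arr.shape[0]):
        for j in range(i + 1, arr.shape[0]):
            both = (arr[i] != gap) & (arr[j] != gap)
            n = int(both.sum())
            if n == 0:
                continue
            vals.append(float((arr[i][both] == arr[j][both]).sum()) / n)
    if not vals:
        raise AlignmentError("no column with two ungapped rows; identity undefined")
    return float(np.mean(vals))


def write_fasta(aln: MultipleAlignment, path: str) -> None:
    with open(path, "w") as fh:
        for taxon, row in zip(aln.taxa, aln.rows):
            fh.write(f">{taxon}\n{row}\n")


def read_fasta_alignment(path: str, source_key: str = "") -> MultipleAlignment:
    from Bio import SeqIO

    taxa, rows = [], []
    for rec in SeqIO.parse(path, "fasta"):
        taxa.append(rec.id)
        rows.append(str(rec.seq).upper())
    return MultipleAlignment(source_key=source_key, taxa=taxa, rows=rows,
                             engine_tag="file")
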