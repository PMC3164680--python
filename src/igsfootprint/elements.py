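"""Functional-element annotation of conserved spacer regions.

Conserved blocks inside intergenic spacers are classified into the element
types expected in a reduced bacterial genome: Shine-Dalgarno ribosome-binding
sites upstream of start codons, rho-independent transcriptional terminators
(G+C-rich hairpin followed by a U-run), bipartite Sigma-32 (RpoH heat-shock
promoter) sites, known sRNAs located by positional orthology to a reference
catalogue, and otherwise-unexplained structured RNAs detected by a
shuffle-based significance test on a base-pairing score.

The built-in fold score is a consensus-weighted Nussinov maximum-pairing
score (pair weights G-C 3, A-T 2, G.U 1, minimum loop 3), averaged over rows
and negated so that lower means more structured.  It is an energy *proxy* in
arbitrary units, not kcal/mol; significance is always relative to shuffles of
the same alignment, so only the ranking within an alignment's shuffle family
matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .align import GAP, MultipleAlignment
from .conservation import ConservedKmer, KmerBlock
from .nullmodel import ShuffleConfig, shuffle_alignment

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

ELEMENT_TYPES = ("SD", "terminator", "sigma32", "known_sRNA", "novel_structured_RNA")

SD_CONSENSUS = "AGGAG"

# Classic enterobacterial RpoH promoter: -35 and -10 boxes with a 13-17 nt
# spacer.  The motif is configuration, not code: load_motif() reads the same
# shape from a TSV.
SIGMA32_DEFAULT = None  # set below once MotifModel exists


@dataclass
class MotifModel:
    name: str
    parts: list[str]                  # IUPAC consensus, 1 (simple) or 2 (bipartite)
    spacer_range: tuple[int, int] = (0, 0)
    max_mismatch: int = 1

    def __post_init__(self) -> None:
        if not self.parts or any(not p for p in self.parts):
            raise ValueError("consensus must be non-empty")
        if self.spacer_range[0] > self.spacer_range[1]:
            raise ValueError("spacer range min > max")


SIGMA32_DEFAULT = MotifModel(
    name="sigma32", parts=["CTTGAA", "CCCCAT"], spacer_range=(13, 17), max_mismatch=2
)


def load_motif(path: str) -> MotifModel:
    """Read a motif file: name, tab-joined consensus parts, spacer range, mm."""
    with open(path) as fh:
        fields = dict(
            line.rstrip("\n").split("\t", 1) for line in fh if line.strip()
        )
    parts = fields["consensus"].split(",")
    lo, hi = (int(x) for x in fields.get("spacer", "0-0").split("-"))
    return MotifModel(
        name=fields.get("name", "motif"),
        parts=parts,
        spacer_range=(lo, hi),
        max_mismatch=int(fields.get("max_mismatch", 1)),
    )


@dataclass
class ElementCall:
    igs_key: tuple
    element_type: str
    alignment_span: tuple[int, int]
    per_taxon: dict[str, tuple[int, int, str]]  # taxon -> (start, end, strand) in spacer
    score: float
    conservation: str  # perfect | near_perfect | partial
    evidence: str = ""
    outside_conserved_block: bool = False


@dataclass
class StructureTestResult:
    igs_key: tuple
    fold_score_actual: float
    shuffled_scores: list[float]
    t_statistic: float
    p: float
    alpha: float
    significant: bool
    untestable: bool = False


# ---------------------------------------------------------------------------
# IUPAC scanning helpers

_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def iupac_mismatches(word: str, consensus: str) -> int:
    return sum(1 for ch, c in zip(word, consensus) if ch not in IUPAC.get(c, ""))


def _scan(seq: str, consensus: str, max_mm: int, lo: int = 0, hi: int | None = None):
    """Yield (start, mismatches) for consensus hits with start in [lo, hi]."""
    hi = len(seq) - len(consensus) if hi is None else hi
    for s in range(max(0, lo), min(hi, len(seq) - len(consensus)) + 1):
        mm = iupac_mismatches(seq[s : s + len(consensus)], consensus)
        if mm <= max_mm:
            yield s, mm


def _hits_to_columns(aln: MultipleAlignment, taxon: str, start: int, end: int):
    """Spacer-position range -> alignment column range for one taxon."""
    posmap = aln.position_map(taxon)
    return int(posmap[start]), int(posmap[end - 1]) + 1


def _cross_taxon_call(aln, per_taxon_hits, igs_key, element_type, evidence=""):
    """Combine per-taxon hits into conserved calls at homologous columns.

    ``per_taxon_hits``: taxon -> list of (start, end, strand, mismatches,
    score).  A call requires one hit per taxon whose alignment column spans
    all mutually overlap; the call span is the union of column spans.
    """
    taxa = list(per_taxon_hits)
    if not taxa or any(not per_taxon_hits[t] for t in taxa):
        return []
    cols = {
        t: [
            (_hits_to_columns(aln, t, h[0], h[1]), h) for h in per_taxon_hits[t]
        ]
        for t in taxa
    }
    calls = []
    used: set[tuple] = set()
    anchor = taxa[0]
    for (a_span, a_hit) in cols[anchor]:
        chosen = {anchor: (a_span, a_hit)}
        lo, hi = a_span
        ok = True
        for t in taxa[1:]:
            best = None
            for span, hit in cols[t]:
                if span[0] < hi and lo < span[1]:  # overlap with anchor span
                    if best is None or hit[3] < best[1][3]:
                        best = (span, hit)
            if best is None:
                ok = False
                break
            chosen[t] = best
        if not ok:
            continue
        span = (
            min(s[0][0] for s in chosen.values()),
            max(s[0][1] for s in chosen.values()),
        )
        if span in used:
            continue
        used.add(span)
        total_mm = sum(h[3] for _, h in chosen.values())
        n_mm_taxa = sum(1 for _, h in chosen.values() if h[3] > 0)
        identical_cols = len({s for s, _ in chosen.values()}) == 1
        if total_mm == 0 and identical_cols:
            conservation = "perfect"
        elif n_mm_taxa <= 1 and all(h[3] <= 1 for _, h in chosen.values()):
            conservation = "near_perfect"
        else:
            conservation = "partial"
        calls.append(
            ElementCall(
                igs_key=igs_key,
                element_type=element_type,
                alignment_span=span,
                per_taxon={t: (h[0], h[1], h[2]) for t, (_, h) in chosen.items()},
                score=float(np.mean([h[4] for _, h in chosen.values()])),
                conservation=conservation,
                evidence=evidence,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# Shine-Dalgarno


def find_sd_sites(
    aln: MultipleAlignment,
    igs_key: tuple = ("", ""),
    anchor: str = "right+",
    consensus: str = SD_CONSENSUS,
    window: tuple[int, int] = (4, 20),
    max_mismatch: int = 1,
) -> list[ElementCall]:
    """Scan for a ribosome-binding (Shine-Dalgarno) motif upstream of a start.

    ``anchor`` names the flanking gene whose start codon abuts this spacer:
    ``right+`` (downstream gene on the forward strand; window measured back
    from the spacer end) or ``left-`` (gene on the reverse strand whose start
    is the spacer start; the reverse complement is scanned).  The motif must
    be present in every row, at mutually overlapping alignment columns; a
    call is ``perfect`` when exact and at identical columns in all taxa, and
    ``near_perfect`` with at most one mismatched taxon.
    """
    w_min, w_max = window
    k = len(consensus)
    per_taxon: dict[str, list] = {}
    for taxon in aln.taxa:
        seq = aln.ungapped(taxon)
        hits = []
        if anchor == "right+":
            lo = len(seq) - w_max - k
            hi = len(seq) - w_min - k
            for s, mm in _scan(seq, consensus, max_mismatch, lo, hi):
                hits.append((s, s + k, "+", mm, k - mm))
        elif anchor == "left-":
            rc = revcomp(seq)
            lo = len(rc) - w_max - k
            hi = len(rc) - w_min - k
            for s, mm in _scan(rc, consensus, max_mismatch, lo, hi):
                fs = len(seq) - (s + k)
                hits.append((fs, fs + k, "-", mm, k - mm))
        else:
            raise ValueError(f"unknown anchor {anchor!r}")
        if not hits:
            return []
        per_taxon[taxon] = hits
    return _cross_taxon_call(aln, per_taxon, igs_key, "SD", evidence=f"consensus={consensus}")


# ---------------------------------------------------------------------------
# rho-independent terminators

_PAIR_W = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "T"): 2, ("T", "A"): 2,
    ("G", "T"): 1, ("T", "G"): 1,
}


def _hairpin_hits(
    seq: str,
    min_stem: int = 4,
    max_stem: int = 10,
    loop_range: tuple[int, int] = (3, 8),
    max_stem_mismatch: int = 1,
    tail_window: int = 7,
    tail_min_t: int = 3,
    tail_within: int = 5,
) -> list[tuple[int, int, str, int, float]]:
    """Single-strand hairpin-plus-U-tail scan; returns (start, end, '+', 0, score)."""
    L = len(seq)
    hits = []
    for i in range(L):
        best_here = None
        for stem in range(min_stem, max_stem + 1):
            for loop in range(loop_range[0], loop_range[1] + 1):
                j = i + stem + loop  # stem2 start
                end = j + stem
                if end > L:
                    break
                mism = 0
                score = 0.0
                paired = 0
                bad = False
                for x in range(stem):
                    a = seq[i + x]
                    b = seq[end - 1 - x]
                    w = _PAIR_W.get((a, b))
                    if w is None:
                        mism += 1
                        if mism > max_stem_mismatch:
                            bad = True
                            break
                    else:
                        score += w
                        paired += 1
                if bad or paired < min_stem - max_stem_mismatch or paired < 3:
                    continue
                tail = seq[end : end + tail_within + tail_window]
                has_tail = any(
                    tail[o : o + tail_window].count("T") >= tail_min_t
                    for o in range(0, max(1, min(tail_within, len(tail)) ))
                    if len(tail[o : o + tail_window]) >= tail_min_t
                )
                if not has_tail:
                    continue
                if best_here is None or score > best_here[4]:
                    best_here = (i, end, "+", 0, score)
        if best_here:
            hits.append(best_here)
    # collapse overlapping candidates, keep the best-scoring representative
    hits.sort(key=lambda h: (-h[4], h[0]))
    kept: list = []
    for h in hits:
        if all(h[1] <= k[0] or k[1] <= h[0] for k in kept):
            kept.append(h)
    kept.sort(key=lambda h: h[0])
    return kept


def find_terminators(
    aln: MultipleAlignment,
    igs_key: tuple = ("", ""),
    strands: Sequence[str] = ("+", "-"),
    **scan_kwargs,
) -> list[ElementCall]:
    """Conserved rho-independent terminators: hairpin (stem >= 4 pairs,
    Watson-Crick or G.U with at most one mismatch, loop 3-8 nt) followed
    within 5 nt by a U-rich tail (>= 3 T in a 7-nt window).

    Hits are required at homologous alignment columns on the same strand in
    every taxon; the score is the summed stem pair weight (G-C 3, A-T 2,
    G.U 1) averaged over taxa.
    """
    calls = []
    for strand in strands:
        per_taxon: dict[str, list] = {}
        all_have = True
        for taxon in aln.taxa:
            seq = aln.ungapped(taxon)
            scan_seq = seq if strand == "+" else revcomp(seq)
            hits = []
            for (s, e, _, mm, score) in _hairpin_hits(scan_seq, **scan_kwargs):
                if strand == "+":
                    hits.append((s, e, "+", mm, score))
                else:
                    hits.append((len(seq) - e, len(seq) - s, "-", mm, score))
            if not hits:
                all_have = False
                break
            per_taxon[taxon] = hits
        if all_have:
            calls.extend(
                _cross_taxon_call(aln, per_taxon, igs_key, "terminator",
                                  evidence=f"strand={strand}")
            )
    return calls


# ---------------------------------------------------------------------------
# Sigma-32 (RpoH) bipartite promoter


def find_sigma32_sites(
    aln: MultipleAlignment,
    igs_key: tuple = ("", ""),
    model: MotifModel | None = None,
) -> list[ElementCall]:
    """Bipartite -35/-10 promoter scan with a bounded spacer.

    Each taxon must carry both boxes with the configured spacer and at most
    ``model.max_mismatch`` total mismatches, at homologous columns across
    taxa; near-perfect cross-taxon conservation is then reported by the
    usual rule.
    """
    m = model or SIGMA32_DEFAULT
    if len(m.parts) == 1:
        p1, p2 = m.parts[0], ""
    else:
        p1, p2 = m.parts[0], m.parts[1]
    per_taxon: dict[str, list] = {}
    for taxon in aln.taxa:
        seq = aln.ungapped(taxon)
        hits = []
        for s1, mm1 in _scan(seq, p1, m.max_mismatch):
            if not p2:
                hits.append((s1, s1 + len(p1), "+", mm1, len(p1) - mm1))
                continue
            for spacer in range(m.spacer_range[0], m.spacer_range[1] + 1):
                s2 = s1 + len(p1) + spacer
                if s2 + len(p2) > len(seq):
                    break
                mm2 = iupac_mismatches(seq[s2 : s2 + len(p2)], p2)
                if mm1 + mm2 <= m.max_mismatch:
                    hits.append(
                        (s1, s2 + len(p2), "+", mm1 + mm2,
                         len(p1) + len(p2) - mm1 - mm2)
                    )
        if not hits:
            return []
        per_taxon[taxon] = hits
    return _cross_taxon_call(aln, per_taxon, igs_key, "sigma32", evidence=m.name)


# ---------------------------------------------------------------------------
# known sRNAs by positional orthology


def load_reference_elements(path: str) -> list[dict]:
    """Reference catalogue TSV: name, sequence, left_ortholog, right_ortholog."""
    rows = []
    with open(path) as fh:
        header = None
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None and parts[0] == "name":
                header = parts
                continue
            if len(parts) < 4:
                raise ValueError(f"{path}:{i + 1}: expected 4 columns")
            rows.append(
                {
                    "name": parts[0],
                    "sequence": parts[1].upper(),
                    "left_ortholog": parts[2],
                    "right_ortholog": parts[3],
                }
            )
    return rows


def match_known_srnas(
    igs_sets: Sequence,
    alignments: Mapping[tuple, MultipleAlignment],
    reference: Sequence[dict],
    min_score_fraction: float = 0.5,
) -> list[ElementCall]:
    """Annotate known sRNAs: sequence similarity plus positional orthology.

    A call requires the reference locus and the spacer to share the same
    flanking ortholog pair, and a seeded local alignment of the reference
    sequence against at least one member to score at least
    ``min_score_fraction`` of the reference length (match +1, mismatch -1,
    gaps -2/-1).
    """
    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="local", match_score=1, mismatch_score=-1,
        open_gap_score=-2, extend_gap_score=-1,
    )
    by_key = {tuple(sorted(s.key)): s for s in igs_sets}
    calls = []
    for ref in reference:
        key = tuple(sorted((ref["left_ortholog"], ref["right_ortholog"])))
        oset = by_key.get(key)
        if oset is None:
            continue
        aln = alignments.get(oset.key)
        threshold = min_score_fraction * len(ref["sequence"])
        best = None
        for taxon, rec in sorted(oset.members.items()):
            if not rec.sequence:
                continue
            score = aligner.score(rec.sequence, ref["sequence"])
            if score >= threshold and (best is None or score > best[1]):
                best = (taxon, score)
        if best is None:
            continue
        span = (0, aln.n_columns) if aln is not None else (0, 0)
        calls.append(
            ElementCall(
                igs_key=oset.key,
                element_type="known_sRNA",
                alignment_span=span,
                per_taxon={
                    t: (0, r.length, "+") for t, r in oset.members.items()
                },
                score=float(best[1]),
                conservation="partial",
                evidence=ref["name"],
            )
        )
    return calls


# ---------------------------------------------------------------------------
# secondary-structure significance (shuffle test)

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}

_W = np.zeros((5, 5))
_W[2, 1] = _W[1, 2] = 3.0  # G-C
_W[0, 3] = _W[3, 0] = 2.0  # A-T
_W[2, 3] = _W[3, 2] = 1.0  # G-U


def _nussinov_py(codes: np.ndarray, w: np.ndarray, min_loop: int) -> float:
    n = len(codes)
    N = np.zeros((n, n))
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = N[i + 1, j - 1] + w[codes[i], codes[j]]
            if N[i + 1, j] > best:
                best = N[i + 1, j]
            if N[i, j - 1] > best:
                best = N[i, j - 1]
            for k in range(i + 1, j):
                v = N[i, k] + N[k + 1, j]
                if v > best:
                    best = v
            N[i, j] = best
    return float(N[0, n - 1]) if n > 1 else 0.0


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    _nussinov_jit = njit(cache=False)(_nussinov_py)

    def _nussinov(codes, w, min_loop):
        return _nussinov_jit(codes, w, min_loop)
except Exception:  # pragma: no cover
    _nussinov = _nussinov_py


def fold_score(seq: str, min_loop: int = 3) -> float:
    """Negated weighted maximum-pairing score; lower = more structured."""
    codes = np.array([_BASE_CODE.get(c, 4) for c in seq.upper()], dtype=np.int64)
    if len(codes) < 2:
        return 0.0
    return -_nussinov(codes, _W, min_loop)


def alignment_fold_score(aln: MultipleAlignment, min_loop: int = 3) -> float:
    return float(np.mean([fold_score(aln.ungapped(t), min_loop) for t in aln.taxa]))


def structure_significance(
    aln: MultipleAlignment,
    igs_key: tuple = ("", ""),
    replicates: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    igs_index: int = 0,
) -> StructureTestResult:
    """Shuffle test for conserved secondary structure.

    The alignment (already trimmed to the conserved block span) is scored,
    then ``replicates`` row-composition-preserving shuffles are scored the
    same way.  The one-sided test asks whether the actual score is lower
    (more structured) than expected: t = (mean_null - actual) /
    (sd_null * sqrt(1 + 1/R)), with p from Student's t on R-1 df.  The
    sqrt(1 + 1/R) term accounts for comparing a single observation against
    a sample mean, keeping p uniform under the null.
    """
    actual = alignment_fold_score(aln)
    cfg = ShuffleConfig(mode="row_residue_permutation", replicates=replicates, seed=seed)
    scores = [
        alignment_fold_score(shuffle_alignment(aln, cfg, rep, igs_index))
        for rep in range(replicates)
    ]
    arr = np.asarray(scores)
    sd = float(arr.std(ddof=1))
    if sd == 0.0:
        return StructureTestResult(
            igs_key, actual, scores, float("nan"), float("nan"), alpha,
            significant=False, untestable=True,
        )
    t = (float(arr.mean()) - actual) / (sd * np.sqrt(1.0 + 1.0 / replicates))
    p = float(stats.t.sf(t, df=replicates - 1))
    return StructureTestResult(
        igs_key, actual, scores, float(t), p, alpha, significant=p < alpha
    )


def dedupe_calls(calls: Sequence[ElementCall]) -> list[ElementCall]:
    """Collapse overlapping same-type calls on one spacer to the best-scoring."""
    kept: list[ElementCall] = []
    for c in sorted(calls, key=lambda c: (-c.score, c.alignment_span)):
        clash = any(
            k.igs_key == c.igs_key
            and k.element_type == c.element_type
            and k.alignment_span[0] < c.alignment_span[1]
            and c.alignment_span[0] < k.alignment_span[1]
            for k in kept
        )
        if not clash:
            kept.append(c)
    kept.sort(key=lambda c: (c.igs_key, c.alignment_span))
    return kept


def restrict_to_conserved(
    calls: Sequence[ElementCall],
    kmers_by_key: Mapping[tuple, Sequence[ConservedKmer]],
    exempt_types: Sequence[str] = ("SD", "known_sRNA"),
) -> list[ElementCall]:
    """Keep only calls whose span intersects a conserved k-mer.

    Elements are sought within conserved alignment blocks; single-motif
    scans (SD) and positional-orthology matches carry their own conservation
    requirement and are exempt.
    """
    out = []
    for c in calls:
        if c.element_type in exempt_types:
            out.append(c)
            continue
        kms = kmers_by_key.get(c.igs_key, ())
        lo, hi = c.alignment_span
        if any(km.start_col < hi and lo < km.end_col for km in kms):
            out.append(c)
    return out


# ---------------------------------------------------------------------------
# collation


def collate_elements(
    igs_keys: Sequence[tuple],
    kmers_by_key: Mapping[tuple, Sequence[ConservedKmer]],
    blocks_by_key: Mapping[tuple, Sequence[KmerBlock]],
    calls: Sequence[ElementCall],
    structure_results: Mapping[tuple, StructureTestResult] | None = None,
) -> dict[tuple, dict]:
    """Per-spacer functional classification.

    Each spacer is labelled with the element types present, whether it has
    conserved k-mers/blocks, and a single display class (first matching of:
    the element types in declaration order, then ``structured``, then
    ``conserved_no_function``, then ``no_conserved_element``).  Calls whose
    span misses every conserved k-mer are flagged ``outside_conserved_block``.
    """
    by_key: dict[tuple, list[ElementCall]] = {}
    for call in calls:
        by_key.setdefault(call.igs_key, []).append(call)
    out = {}
    for key in igs_keys:
        kms = list(kmers_by_key.get(key, ()))
        blocks = list(blocks_by_key.get(key, ()))
        key_calls = by_key.get(key, [])
        for call in key_calls:
            lo, hi = call.alignment_span
            call.outside_conserved_block = not any(
                km.start_col < hi and lo < km.end_col for km in kms
            )
        types = sorted({c.element_type for c in key_calls})
        structured = bool(
            structure_results
            and key in structure_results
            and structure_results[key].significant
        )
        if types:
            cls = next(t for t in ELEMENT_TYPES if t in types)
        elif structured:
            cls = "structured"
        elif kms:
            cls = "conserved_no_function"
        else:
            cls = "no_conserved_element"
        out[key] = {
            "element_types": types,
            "has_kmer": bool(kms),
            "has_block": bool(blocks),
            "structured": structured,
            "classification": cls,
            "n_calls": len(key_calls),
            "has_function": bool(types) or structured,
        }
    return out


def write_element_table(calls: Sequence[ElementCall], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "igs_key\telement_type\tspan_start\tspan_end\tscore\t"
            "conservation\tevidence\tper_taxon\n"
        )
        for c in calls:
            pt = ";".join(
                f"{t}:{s}-{e}{st}" for t, (s, e, st) in sorted(c.per_taxon.items())
            )
            fh.write(
                f"{'|'.join(c.igs_key)}\t{c.element_type}\t{c.alignment_span[0]}\t"
                f"{c.alignment_span[1]}\t{c.score:.2f}\t{c.conservation}\t"
                f"{c.evidence}\t{pt}\n"
            )
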