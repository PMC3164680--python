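"""Gene erosion: pseudogene calling, event mapping, and coding divergence.

In clonal endosymbionts gene decay is effectively irreversible: an intact
gene can become a pseudogene (inactivating mutation) and a pseudogene can be
deleted, but remnants are never resurrected.  Event reconstruction therefore
uses a Dollo-style minimum-event mapping on a fixed species tree with the
state order intact -> pseudogene -> absent and no reversals; ties are broken
toward terminal branches, so a disruption seen in a single genome is placed
on that genome's own branch.

Pairwise coding divergence uses the Nei-Gojobori (1986) counting method:
per-codon synonymous/nonsynonymous site fractions (changes creating stop
codons count as nonsynonymous), pathway-averaged difference counts for
multi-hit codons (pathways through stop codons excluded when any stop-free
pathway exists), and the Jukes-Cantor multiple-hit correction.  The
correction diverges as p approaches 3/4; p_s >= 0.749 is reported as a
saturated (inestimable) Ks, the regime in which perfect k-mer conservation
becomes informative.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .align import AlignParams, GAP, align_profiles

STATES = ("intact", "pseudogene", "absent")
_STATE_IDX = {s: i for i, s in enumerate(STATES)}
_STOPS = {"TAA", "TAG", "TGA"}
_STARTS = {"ATG", "GTG", "TTG"}

_INF = float("inf")
# transition cost matrix under irreversibility; rows parent, cols child
_TRANS = np.array(
    [
        [0.0, 1.0, 1.0],   # intact -> intact / pseudogene / absent(one loss)
        [_INF, 0.0, 1.0],  # pseudogene -> ...
        [_INF, _INF, 0.0], # absent -> absent only
    ]
)


class ErosionError(ValueError):
    pass


@dataclass
class PseudogeneCall:
    ortholog_id: str
    taxon_id: str
    fraction_length_retained: float
    inactivating_mutations: int
    mutation_classes: list[str]
    homopolymeric_frameshift: bool
    coordinates: tuple[int, int] | None = None

    @property
    def mutation_class_label(self) -> str:
        n = self.inactivating_mutations
        return "1 mutation" if n <= 1 else ("2 mutations" if n == 2 else ">=3 mutations")


@dataclass
class EventMap:
    branch_events: dict[str, dict[str, int]]  # branch label -> event type -> count
    placements: dict[str, list[tuple[str, str]]]  # ortholog -> [(branch, event)]
    total_events: int


@dataclass
class DivergenceEstimate:
    taxon_pair: tuple[str, str]
    ortholog_id: str
    ka: float
    ks: float | None
    saturated: bool
    s_sites: float = 0.0
    n_sites: float = 0.0


# ---------------------------------------------------------------------------
# pseudogene calling


def detect_homopolymer_context(
    reference: str, indel_position: int, run_min: int = 6
) -> bool:
    """True iff an indel at ``indel_position`` (reference coordinate) falls
    inside a mononucleotide run of at least ``run_min`` in the reference."""
    if not (0 <= indel_position <= len(reference)):
        raise ErosionError(f"indel position {indel_position} outside reference")
    pos = min(indel_position, len(reference) - 1)
    base = reference[pos]
    left = pos
    while left > 0 and reference[left - 1] == base:
        left -= 1
    right = pos
    while right + 1 < len(reference) and reference[right + 1] == base:
        right += 1
    return (right - left + 1) >= run_min


def _check_intact_reference(reference: str) -> None:
    if len(reference) % 3 != 0:
        raise ErosionError("reference CDS length not divisible by 3")
    if reference[:3] not in _STARTS:
        raise ErosionError(f"reference does not start with a start codon")
    if reference[-3:] not in _STOPS:
        raise ErosionError("reference does not end with a stop codon")
    for i in range(0, len(reference) - 3, 3):
        if reference[i : i + 3] in _STOPS:
            raise ErosionError(f"reference has internal stop at codon {i // 3}")


def call_pseudogene(
    candidate_nt: str,
    reference_cds: str,
    ortholog_id: str = "",
    taxon_id: str = "",
    run_min: int = 6,
    length_threshold: float = 0.8,
) -> PseudogeneCall | str:
    """Classify a candidate sequence against an intact reference homolog.

    Returns ``"intact"`` when no inactivating mutation is found and the
    undisrupted reading frame retains at least ``length_threshold`` of the
    reference length; ``"absent"`` for an empty candidate; otherwise a
    :class:`PseudogeneCall` enumerating premature stops, frameshifting
    indels (gap runs of length not divisible by three in the pairwise
    alignment) and truncation.
    """
    reference_cds = reference_cds.upper()
    candidate_nt = candidate_nt.upper()
    _check_intact_reference(reference_cds)
    if not candidate_nt:
        return "absent"
    (ra,), (ca,) = align_profiles(
        [reference_cds], [candidate_nt], AlignParams(match=1, mismatch=-1,
                                                     gap_open=-6, gap_extend=-1)
    )
    # enumerate indel events with reference coordinates
    events = []  # (ref_pos, length, kind)  kind: 'del' gap in candidate, 'ins'
    ref_pos = 0
    i = 0
    L = len(ra)
    while i < L:
        if ca[i] == GAP and ra[i] != GAP:
            j = i
            while j < L and ca[j] == GAP and ra[j] != GAP:
                j += 1
            events.append((ref_pos, j - i, "del"))
            ref_pos += j - i
            i = j
        elif ra[i] == GAP and ca[i] != GAP:
            j = i
            while j < L and ra[j] == GAP and ca[j] != GAP:
                j += 1
            events.append((ref_pos, j - i, "ins"))
            i = j
        else:
            ref_pos += 1
            i += 1
    # ignore terminal overhangs (truncation, scored via length fraction)
    body_events = [
        (p, ln, kind)
        for p, ln, kind in events
        if p > 0
        and (p + (ln if kind == "del" else 0)) < len(reference_cds)
    ]
    frameshifts = [(p, ln, kind) for p, ln, kind in body_events if ln % 3 != 0]
    # premature stops in reference-projected codons (cleanly aligned codons)
    ref_cols = [i for i in range(L) if ra[i] != GAP]
    premature_stops = []
    n_codons = len(reference_cds) // 3
    for ci in range(n_codons - 1):  # exclude the terminal stop codon
        cols = ref_cols[3 * ci : 3 * ci + 3]
        cod = "".join(ca[c] for c in cols)
        if cod in _STOPS and cod != reference_cds[3 * ci : 3 * ci + 3]:
            premature_stops.append(ci)
    mutations = len(frameshifts) + len(premature_stops)
    # fraction of reference length retained before the first disruption
    if mutations:
        first = min(
            [p // 3 for p, _, _ in frameshifts] + premature_stops
        )
        fraction = first / n_codons
    else:
        aligned_ref = sum(1 for i in range(L) if ra[i] != GAP and ca[i] != GAP)
        fraction = aligned_ref / len(reference_cds)
    if mutations == 0 and fraction >= length_threshold:
        return "intact"
    classes = []
    classes.extend("premature_stop" for _ in premature_stops)
    classes.extend("frameshift" for _ in frameshifts)
    if mutations == 0:
        classes.append("truncation")
    homopoly = any(
        detect_homopolymer_context(reference_cds, p, run_min) for p, _, _ in frameshifts
    )
    return PseudogeneCall(
        ortholog_id=ortholog_id,
        taxon_id=taxon_id,
        fraction_length_retained=fraction,
        inactivating_mutations=max(mutations, 1),
        mutation_classes=classes,
        homopolymeric_frameshift=homopoly,
    )


# ---------------------------------------------------------------------------
# gene state matrix and event mapping


def build_state_matrix(
    genomes: Sequence,
    pseudogene_calls: Mapping[tuple[str, str], object] | None = None,
) -> dict[str, dict[str, str]]:
    """State per (ortholog, taxon): intact / pseudogene / absent.

    A feature annotated as CDS counts intact unless a pseudogene call for
    (ortholog, taxon) overrides it; an annotated pseudogene is a pseudogene;
    no feature mapping to the ortholog means absent.
    """
    calls = pseudogene_calls or {}
    orthologs: set[str] = set()
    per_taxon: dict[str, dict[str, str]] = {}
    for genome in genomes:
        states: dict[str, str] = {}
        for f in genome.features:
            if f.ortholog_id is None:
                continue
            orthologs.add(f.ortholog_id)
            if f.kind == "pseudogene":
                if states.get(f.ortholog_id) == "intact":
                    raise ErosionError(
                        f"{genome.taxon_id}:{f.ortholog_id} annotated both CDS "
                        "and pseudogene"
                    )
                states[f.ortholog_id] = "pseudogene"
            elif f.kind == "CDS":
                if states.get(f.ortholog_id) == "pseudogene":
                    raise ErosionError(
                        f"{genome.taxon_id}:{f.ortholog_id} annotated both CDS "
                        "and pseudogene"
                    )
                states[f.ortholog_id] = "intact"
            else:
                states.setdefault(f.ortholog_id, "intact")
        per_taxon[genome.taxon_id] = states
    matrix: dict[str, dict[str, str]] = {}
    for oid in sorted(orthologs):
        row = {}
        for taxon, states in per_taxon.items():
            st = states.get(oid, "absent")
            call = calls.get((oid, taxon))
            if call is not None and call != "intact" and st == "intact":
                st = "pseudogene"
            row[taxon] = st
        matrix[oid] = row
    return matrix


def _tree_children(tree) -> tuple[dict, object, dict]:
    """Adjacency and labels from a dendropy tree."""
    labels = {}
    for i, node in enumerate(tree.preorder_node_iter()):
        if node.is_leaf():
            labels[node] = node.taxon.label
        else:
            labels[node] = node.label or f"node{i}"
    return labels, tree.seed_node, {
        n: list(n.child_nodes()) for n in tree.preorder_node_iter()
    }


def map_events(
    matrix: Mapping[str, Mapping[str, str]], tree
) -> EventMap:
    """Minimum-event Dollo mapping of gene states onto a fixed phylogeny.

    ``tree`` is a rooted dendropy tree (polytomies allowed) whose leaf labels
    equal the matrix taxa.  Per ortholog a Sankoff pass finds the cheapest
    assignment of {intact, pseudogene, absent} to internal nodes under the
    irreversible transition costs; on ties internal nodes prefer the less
    derived state, which pushes events toward the tips.  Branches are
    labelled by their child node (leaf name or internal node label).
    """
    labels, root, children = _tree_children(tree)
    leaves = {labels[n] for n in children if not children[n]}
    branch_events: dict[str, dict[str, int]] = {}
    placements: dict[str, list[tuple[str, str]]] = {}
    total = 0
    event_name = {
        (0, 1): "inactivation",
        (0, 2): "loss",
        (1, 2): "pseudogene_deletion",
    }
    for oid, row in matrix.items():
        missing = leaves - set(row)
        if missing:
            raise ErosionError(f"{oid}: taxa missing from matrix: {sorted(missing)}")
        extra = set(row) - leaves
        if extra:
            raise ErosionError(f"{oid}: taxa not in tree: {sorted(extra)}")
        cost: dict[object, np.ndarray] = {}
        for node in reversed(list(_preorder(root, children))):
            if not children[node]:
                c = np.full(3, _INF)
                c[_STATE_IDX[row[labels[node]]]] = 0.0
                cost[node] = c
            else:
                c = np.zeros(3)
                for ch in children[node]:
                    c += np.min(_TRANS + cost[ch][None, :], axis=1)
                cost[node] = c
        # choose root state: min cost, ties toward the least derived state
        root_state = int(np.argmin(cost[root]))  # argmin takes first == intact first
        events: list[tuple[str, str]] = []

        def assign(node, state: int) -> None:
            for ch in children[node]:
                opts = _TRANS[state] + cost[ch]
                ch_state = int(np.argmin(opts))  # ties -> least derived
                if ch_state != state and np.isfinite(_TRANS[state, ch_state]):
                    events.append((labels[ch], event_name[(state, ch_state)]))
                assign(ch, ch_state)

        assign(root, root_state)
        if events:
            placements[oid] = events
        for branch, ev in events:
            branch_events.setdefault(branch, {}).setdefault(ev, 0)
            branch_events[branch][ev] += 1
            total += 1
    return EventMap(branch_events=branch_events, placements=placements,
                    total_events=total)


def _preorder(root, children):
    stack = [root]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(reversed(children[n]))


def count_events(matrix_row: Mapping[str, str], tree) -> int:
    """Minimum event count for a single ortholog's state pattern."""
    em = map_events({"x": matrix_row}, tree)
    return em.total_events


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986) Ka/Ks

_CODON_TABLE: dict[str, str] = {}


def _codon_table() -> dict[str, str]:
    if not _CODON_TABLE:
        from Bio.Seq import Seq

        for b1 in "TCAG":
            for b2 in "TCAG":
                for b3 in "TCAG":
                    cod = b1 + b2 + b3
                    _CODON_TABLE[cod] = str(Seq(cod).translate())
    return _CODON_TABLE


def _codon_sites(codon: str) -> tuple[float, float]:
    """Synonymous / nonsynonymous site fractions of one codon.

    Changes creating stop codons count as nonsynonymous (the published
    counting convention); every codon contributes exactly three sites.
    """
    table = _codon_table()
    aa = table[codon]
    syn = 0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if table[alt] != "*" and table[alt] == aa:
                syn += 1
    s = syn / 3.0
    return s, 3.0 - s


def _path_counts(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous difference counts."""
    table = _codon_table()
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if table[nxt] == "*":
                through_stop = True
            if table[cur] == table[nxt] and table[nxt] != "*":
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd, through_stop))
    clean = [(s, n) for s, n, stop in paths if not stop]
    use = clean if clean else [(s, n) for s, n, _ in paths]
    sd = float(np.mean([s for s, _ in use]))
    nd = float(np.mean([n for _, n in use]))
    return sd, nd


def estimate_ka_ks(
    seq1: str,
    seq2: str,
    taxon_pair: tuple[str, str] = ("a", "b"),
    ortholog_id: str = "",
    saturation_p: float = 0.749,
) -> DivergenceEstimate:
    """Counting-method Ka/Ks on a gap-free pairwise codon alignment.

    Both sequences must be equal-length, length divisible by three; gapped
    codon columns (a gap anywhere in the codon in either row) and codons
    containing ambiguity codes are skipped.  At least 10 comparable codons
    are required.
    """
    seq1, seq2 = seq1.upper(), seq2.upper()
    if len(seq1) != len(seq2):
        raise ErosionError("sequences must be aligned (equal length)")
    if len(seq1) % 3 != 0:
        raise ErosionError("aligned length not divisible by 3")
    table = _codon_table()
    s_sites = n_sites = 0.0
    sd = nd = 0.0
    n_codons = 0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        if any(ch not in "ACGT" for ch in c1 + c2):
            continue
        if table[c1] == "*" or table[c2] == "*":
            continue
        n_codons += 1
        s1, n1 = _codon_sites(c1)
        s2, n2 = _codon_sites(c2)
        s_sites += (s1 + s2) / 2.0
        n_sites += (n1 + n2) / 2.0
        dsd, dnd = _path_counts(c1, c2)
        sd += dsd
        nd += dnd
    if n_codons < 10:
        raise ErosionError(f"only {n_codons} comparable codons (need >= 10)")
    ps = sd / s_sites if s_sites else 0.0
    pn = nd / n_sites if n_sites else 0.0

    def jc(p: float) -> float | None:
        if p >= saturation_p:
            return None
        return -0.75 * np.log(1.0 - 4.0 * p / 3.0)

    ks = jc(ps)
    ka = jc(pn)
    return DivergenceEstimate(
        taxon_pair=tuple(taxon_pair),
        ortholog_id=ortholog_id,
        ka=float(ka) if ka is not None else float("nan"),
        ks=float(ks) if ks is not None else None,
        saturated=ks is None,
        s_sites=s_sites,
        n_sites=n_sites,
    )


def write_event_table(em: EventMap, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("branch\tinactivations\tlosses\tpseudogene_deletions\n")
        for branch in sorted(em.branch_events):
            ev = em.branch_events[branch]
            fh.write(
                f"{branch}\t{ev.get('inactivation', 0)}\t{ev.get('loss', 0)}\t"
                f"{ev.get('pseudogene_deletion', 0)}\n"
            )


def write_state_matrix(matrix: Mapping[str, Mapping[str, str]], path: str) -> None:
    taxa = sorted({t for row in matrix.values() for t in row})
    with open(path, "w") as fh:
        fh.write("ortholog_id\t" + "\t".join(taxa) + "\n")
        for oid in sorted(matrix):
            fh.write(oid + "\t" + "\t".join(matrix[oid][t] for t in taxa) + "\n")
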