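"""Synthetic evolution of spacers, coding genes and whole toy genomes.

The generator emulates the statistical regime of reduced, AT-rich
endosymbiont genomes so every pipeline stage can be tested hermetically
against planted ground truth:

* spacers evolve under an AT-biased HKY substitution process (stationary
  G+C 0.15, transition/transversion ratio 2) on a four-taxon tree deep
  enough that neutral pairwise identity averages ~0.52 — divergences at
  which neutral sequence is saturated but perfectly conserved elements
  stand out;
* planted elements (ribosome-binding motifs, terminator hairpins, arbitrary
  library sequences) substitute at ``omega_element`` times the neutral rate
  and are shielded from indels, the footprinting premise that functional
  elements resist both substitution and deletion;
* neutral sites experience deletion-biased indels (deletion:insertion 3:1,
  geometric lengths);
* coding sequences evolve with per-codon-position rate multipliers that
  keep amino-acid divergence low while saturating third positions,
  reproducing the low-Ka / inestimable-Ks contrast of the study system.

Every draw flows from one ``numpy`` generator seeded from the config, so
identical configs give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy.linalg import expm

from .genome import GeneFeature, GenomeAnnotation

BASES = "ACGT"
_B2I = {b: i for i, b in enumerate(BASES)}
_STOPS = {"TAA", "TAG", "TGA"}

# Four-taxon tree mirroring an Aphidinae-like divergence ladder; root-to-leaf
# depth ~0.9 expected substitutions/site, giving mean pairwise neutral
# identity ~0.52 under the default composition.
DEFAULT_TREE = "(Sg:0.75,(Ua:0.45,(Ak:0.25,Ap:0.25)AkAp:0.15)UaAkAp:0.15)root;"

SD_ELEMENT = "AGGAG"
TERMINATOR_ELEMENT = "GCCGCCTTTTGGCGGCTTTTTTT"  # 6-bp stem, 4-nt loop, U-tail


@dataclass
class SimulationConfig:
    tree_newick: str = DEFAULT_TREE
    gc_target_igs: float = 0.15
    gc_target_cds: float = 0.26
    omega_element: float = 0.02
    site_class_rates_cds: tuple[float, float, float] = (0.05, 0.02, 5.0)
    indel_rate: float = 0.05          # events per substitution per site
    deletion_bias: float = 3.0        # deletions per insertion
    indel_mean_length: float = 3.0
    kappa: float = 2.0
    n_igs: int = 40
    igs_length_range: tuple[int, int] = (80, 400)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.gc_target_igs < 1 and 0 < self.gc_target_cds < 1):
            raise ValueError("gc targets must be in (0,1)")
        for r in (self.omega_element, self.indel_rate, self.deletion_bias,
                  *self.site_class_rates_cds):
            if r < 0:
                raise ValueError("rates must be >= 0")

    def tree(self) -> dendropy.Tree:
        t = dendropy.Tree.get(data=self.tree_newick, schema="newick")
        if len(t.leaf_nodes()) < 2:
            raise ValueError("tree needs >= 2 leaves")
        return t


@dataclass
class PlantedElement:
    element_id: str
    element_type: str      # SD | terminator | library
    sequence: str
    per_taxon: dict[str, tuple[int, int]] = field(default_factory=dict)


@dataclass
class SyntheticTruth:
    elements: dict[str, list[PlantedElement]] = field(default_factory=dict)
    events: list[tuple[str, str, str]] = field(default_factory=list)
    # (ortholog_id, branch_label, kind: inactivation|loss)


# ---------------------------------------------------------------------------
# substitution machinery


def hky_rate_matrix(gc: float, kappa: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """HKY85 rate matrix normalised to one expected substitution per unit time."""
    pi = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}
    Q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i != j:
                Q[i, j] = pi[j] * (kappa if (i, j) in transitions else 1.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()
    return Q / mu, pi


def _sample_transitions(seq: np.ndarray, P: np.ndarray, rng) -> np.ndarray:
    """Draw the state of every site after a branch with transition matrix P."""
    cum = np.cumsum(P, axis=1)
    u = rng.random(len(seq))
    return (u[:, None] > cum[seq]).sum(axis=1).astype(np.int8)


def _encode(seq: str) -> np.ndarray:
    return np.array([_B2I[c] for c in seq], dtype=np.int8)


def _decode(arr: np.ndarray) -> str:
    return "".join(BASES[i] for i in arr)


# ---------------------------------------------------------------------------
# spacer evolution


def _apply_indels(
    seq: np.ndarray,
    spans: list[list],
    t: float,
    cfg: SimulationConfig,
    pi: np.ndarray,
    rng,
) -> np.ndarray:
    """Deletion-biased indels on neutral sites; element spans are immune."""
    n_events = rng.poisson(cfg.indel_rate * t * len(seq))
    p_del = cfg.deletion_bias / (1.0 + cfg.deletion_bias)
    for _ in range(n_events):
        if len(seq) == 0:
            break
        is_del = rng.random() < p_del
        length = int(rng.geometric(1.0 / cfg.indel_mean_length))
        placed = False
        for _attempt in range(30):
            pos = int(rng.integers(0, len(seq) + (0 if is_del else 1)))
            lo, hi = (pos, pos + length) if is_del else (pos, pos)
            if is_del and hi > len(seq):
                continue
            if any(s[1] < (hi if is_del else pos + 1) and (lo if is_del else pos - 1) < s[2]
                   for s in spans):
                continue
            placed = True
            break
        if not placed:
            continue
        if is_del:
            seq = np.concatenate([seq[:pos], seq[pos + length :]])
            for s in spans:
                if s[1] >= pos + length:
                    s[1] -= length
                    s[2] -= length
        else:
            ins = rng.choice(4, size=length, p=pi).astype(np.int8)
            seq = np.concatenate([seq[:pos], ins, seq[pos:]])
            for s in spans:
                if s[1] >= pos:
                    s[1] += length
                    s[2] += length
    return seq


def _evolve_igs(
    node,
    seq: np.ndarray,
    spans: list[list],
    cfg: SimulationConfig,
    Q: np.ndarray,
    pi: np.ndarray,
    rng,
    leaves: dict,
    leaf_spans: dict,
    decay: Mapping[str, set] | None,
) -> None:
    for child in node.child_nodes():
        t = child.edge.length or 0.0
        label = child.taxon.label if child.is_leaf() else (child.label or "")
        child_spans = [list(s) for s in spans]
        if decay and label in decay:
            gone = decay[label]
            child_spans = [
                s for s in child_spans
                if s[0] not in gone and s[0].rsplit(".spacing", 1)[0] not in gone
            ]
        if t > 0:
            P = expm(Q * t)
            Pe = expm(Q * t * cfg.omega_element)
            new = _sample_transitions(seq, P, rng)
            shield = np.zeros(len(seq), dtype=bool)
            for s in child_spans:
                if s[3] == "element":
                    shield[s[1] : s[2]] = True
            if shield.any():
                new[shield] = _sample_transitions(seq[shield], Pe, rng)
            new = _apply_indels(new, child_spans, t, cfg, pi, rng)
        else:
            new = seq.copy()
        if child.is_leaf():
            leaves[child.taxon.label] = new
            leaf_spans[child.taxon.label] = child_spans
        else:
            _evolve_igs(child, new, child_spans, cfg, Q, pi, rng, leaves,
                        leaf_spans, decay)


def simulate_igs_set(
    cfg: SimulationConfig,
    length: int | None = None,
    elements: Sequence[tuple[str, str, int]] = (),
    rng: np.random.Generator | None = None,
    igs_id: str = "igs",
    decay_on_branch: Mapping[str, set] | None = None,
) -> tuple[dict[str, str], list[PlantedElement]]:
    """Evolve one orthologous spacer set down the tree.

    ``elements`` lists (element_type, sequence, root_position) to plant in
    the root sequence; they substitute at ``omega_element`` x the neutral
    rate and indels never touch them.  ``decay_on_branch`` maps a branch
    label to the set of element ids that become neutral from that branch on
    (used to create depth-restricted conservation).  Returns per-taxon
    sequences and the planted-element truth with per-taxon coordinates.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    Q, pi = hky_rate_matrix(cfg.gc_target_igs, cfg.kappa)
    lo, hi = cfg.igs_length_range
    L = length if length is not None else int(rng.integers(lo, hi + 1))
    root = rng.choice(4, size=L, p=pi).astype(np.int8)
    spans: list[list] = []
    planted: dict[str, PlantedElement] = {}
    for i, (etype, eseq, pos) in enumerate(elements):
        pos = max(0, min(pos, L - len(eseq)))
        root[pos : pos + len(eseq)] = _encode(eseq)
        eid = f"{igs_id}.e{i}"
        spans.append([eid, pos, pos + len(eseq), "element"])
        if etype == "SD":
            # ribosome-binding spacing is functionally constrained: the gap
            # between the motif and the start codon keeps its length (no
            # indels) while its sequence stays neutral
            spans.append([f"{eid}.spacing", pos + len(eseq), L, "spacing"])
        planted[eid] = PlantedElement(eid, etype, eseq)
    leaves: dict[str, np.ndarray] = {}
    leaf_spans: dict[str, list] = {}
    tree = cfg.tree()
    _evolve_igs(tree.seed_node, root, spans, cfg, Q, pi, rng, leaves,
                leaf_spans, decay_on_branch)
    seqs = {t: _decode(a) for t, a in leaves.items()}
    for taxon, sp in leaf_spans.items():
        for eid, s, e, kind in sp:
            if kind == "element":
                planted[eid].per_taxon[taxon] = (s, e)
    return seqs, list(planted.values())


# ---------------------------------------------------------------------------
# coding-sequence evolution


def _random_cds(n_codons: int, pi: np.ndarray, rng) -> np.ndarray:
    arr = rng.choice(4, size=3 * n_codons, p=pi).astype(np.int8)
    _fix_stops(arr, keep_terminal=False)
    return arr


def _fix_stops(arr: np.ndarray, keep_terminal: bool, ref: np.ndarray | None = None):
    """Replace internal stop codons (revert to ref, else recode position 2)."""
    n = len(arr) // 3
    last = n if not keep_terminal else n - 1
    for ci in range(last):
        cod = "".join(BASES[b] for b in arr[3 * ci : 3 * ci + 3])
        if cod in _STOPS:
            if ref is not None:
                arr[3 * ci : 3 * ci + 3] = ref[3 * ci : 3 * ci + 3]
            else:
                arr[3 * ci + 2] = _B2I["C"]


def simulate_cds_set(
    cfg: SimulationConfig,
    n_codons: int = 100,
    rng: np.random.Generator | None = None,
    with_stop: bool = True,
    start_codon: bool = True,
) -> dict[str, str]:
    """Evolve an intact coding gene down the tree.

    Codon positions substitute at the configured per-position multipliers
    (defaults slow positions 1-2, saturate position 3); substitutions
    creating internal stop codons are rejected (reverted).
    """
    if n_codons < 10:
        raise ValueError("n_codons must be >= 10")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    Q, pi = hky_rate_matrix(cfg.gc_target_cds, cfg.kappa)
    root = _random_cds(n_codons, pi, rng)
    if start_codon:
        root[0:3] = _encode("ATG")
    pos_class = np.tile([0, 1, 2], n_codons)
    leaves: dict[str, np.ndarray] = {}

    def walk(node, seq):
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            if t > 0:
                new = seq.copy()
                for c, rate in enumerate(cfg.site_class_rates_cds):
                    if rate <= 0:
                        continue
                    P = expm(Q * t * rate)
                    idx = pos_class == c
                    new[idx] = _sample_transitions(seq[idx], P, rng)
                if start_codon:
                    new[0:3] = _encode("ATG")
                _fix_stops(new, keep_terminal=False, ref=seq)
                if (new[:3 * (len(new)//3)].reshape(-1, 3) < 0).any():
                    raise AssertionError
            else:
                new = seq.copy()
            if child.is_leaf():
                leaves[child.taxon.label] = new
            else:
                walk(child, new)

    walk(cfg.tree().seed_node, root)
    suffix = "TAA" if with_stop else ""
    return {t: _decode(a) + suffix for t, a in leaves.items()}


# ---------------------------------------------------------------------------
# whole toy genomes


def _descendant_leaves(tree: dendropy.Tree, branch_label: str) -> set[str]:
    for node in tree.preorder_node_iter():
        label = node.taxon.label if node.is_leaf() else node.label
        if label == branch_label:
            return {lf.taxon.label for lf in node.leaf_iter()}
    raise ValueError(f"branch {branch_label!r} not found in tree")


def build_synthetic_genomes(
    cfg: SimulationConfig,
    n_genes: int = 12,
    n_codons_range: tuple[int, int] = (60, 120),
    sd_fraction: float = 0.5,
    terminator_fraction: float = 0.3,
    inactivations: Sequence[tuple[int, str, str]] = (),
) -> tuple[list[GenomeAnnotation], dict[tuple[str, str], str], SyntheticTruth]:
    """Toy annotated genomes with conserved gene order and planted truth.

    Genes ``g000..`` alternate with spacers; strands are drawn once and
    shared by all taxa.  A fraction of spacers preceding a forward-strand
    gene carry a planted ribosome-binding motif in the scan window, and a
    fraction following a forward-strand gene carry a terminator hairpin.
    ``inactivations`` lists (gene_index, branch_label, kind) with kind
    ``frameshift`` (1-nt deletion inside a planted homopolymeric run),
    ``stop`` (premature stop codon) or ``loss`` (gene removed outright) to
    apply in every taxon descending from the branch.

    Returns the genomes, the (taxon, feature_id) -> ortholog_id map, and the
    complete truth table.
    """
    rng = np.random.default_rng(cfg.seed)
    tree = cfg.tree()
    taxa = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    truth = SyntheticTruth()
    strands = ["+" if rng.random() < 0.5 else "-" for _ in range(n_genes)]
    genes: list[dict[str, str]] = []
    run_pos: dict[int, int] = {}
    inact_by_gene: dict[int, list[tuple[str, str]]] = {}
    for gi, branch, kind in inactivations:
        inact_by_gene.setdefault(gi, []).append((branch, kind))
    for gi in range(n_genes):
        n_cod = int(rng.integers(*n_codons_range))
        cds = simulate_cds_set(cfg, n_cod, rng=rng)
        if gi in inact_by_gene:
            # plant a homopolymeric run (two lysine codons) mid-gene in every
            # taxon so frameshift events have a run >= 6 to land in
            ci = n_cod // 2
            for t in taxa:
                s = cds[t]
                cds[t] = s[: 3 * ci] + "AAAAAA" + s[3 * ci + 6 :]
            run_pos[gi] = 3 * ci
        genes.append(cds)
    # apply inactivation events
    for gi, events in inact_by_gene.items():
        for branch, kind in events:
            affected = _descendant_leaves(tree, branch)
            truth.events.append((f"og{gi:03d}", branch, kind))
            for t in affected:
                s = genes[gi][t]
                if kind == "frameshift":
                    p = run_pos[gi]
                    genes[gi][t] = s[:p] + s[p + 1 :]
                elif kind == "stop":
                    ci = (len(s) // 3) // 3
                    genes[gi][t] = s[: 3 * ci] + "TAA" + s[3 * ci + 3 :]
                elif kind == "loss":
                    genes[gi][t] = ""
                else:
                    raise ValueError(f"unknown event kind {kind!r}")
    # spacers with planted elements
    igs_seqs: list[dict[str, str]] = []
    for si in range(n_genes + 1):
        L = int(rng.integers(*cfg.igs_length_range))
        elements = []
        right_gene = si if si < n_genes else None
        left_gene = si - 1 if si > 0 else None
        if (
            right_gene is not None
            and strands[right_gene] == "+"
            and rng.random() < sd_fraction
        ):
            pos = L - len(SD_ELEMENT) - int(rng.integers(5, 15))
            elements.append(("SD", SD_ELEMENT, pos))
        if (
            left_gene is not None
            and strands[left_gene] == "+"
            and rng.random() < terminator_fraction
        ):
            pos = int(rng.integers(3, max(4, L // 3)))
            elements.append(("terminator", TERMINATOR_ELEMENT, pos))
        seqs, planted = simulate_igs_set(
            cfg, length=L, elements=elements, rng=rng, igs_id=f"igs{si:03d}"
        )
        igs_seqs.append(seqs)
        if planted:
            left_key = f"og{left_gene:03d}" if left_gene is not None else "START"
            right_key = f"og{right_gene:03d}" if right_gene is not None else "END"
            truth.elements[f"{left_key}|{right_key}"] = planted
    # assemble per-taxon contigs
    genomes = []
    ortholog_map: dict[tuple[str, str], str] = {}
    for taxon in taxa:
        parts = []
        features = []
        pos = 0
        for gi in range(n_genes):
            spacer = igs_seqs[gi][taxon]
            parts.append(spacer)
            pos += len(spacer)
            cds = genes[gi][taxon]
            if not cds:
                continue  # lost gene: neighbouring spacers merge
            fid = f"{taxon}_g{gi:03d}"
            seq = cds if strands[gi] == "+" else _revcomp(cds)
            features.append(
                GeneFeature(
                    feature_id=fid,
                    contig_id="chr",
                    start=pos,
                    end=pos + len(seq),
                    strand=strands[gi],
                    kind="CDS",
                    ortholog_id=f"og{gi:03d}",
                )
            )
            ortholog_map[(taxon, fid)] = f"og{gi:03d}"
            parts.append(seq)
            pos += len(seq)
        parts.append(igs_seqs[n_genes][taxon])
        genomes.append(
            GenomeAnnotation(taxon, {"chr": "".join(parts)}, features)
        )
    return genomes, ortholog_map, truth


_RC = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


# ---------------------------------------------------------------------------
# fixture export


def write_fixtures(
    genomes: Sequence[GenomeAnnotation],
    ortholog_map: Mapping[tuple[str, str], str],
    truth: SyntheticTruth,
    outdir: str,
) -> None:
    """Emit FASTA + GFF3 per genome, the ortholog map TSV and truth JSON."""
    import json
    import os

    os.makedirs(outdir, exist_ok=True)
    for g in genomes:
        with open(os.path.join(outdir, f"{g.taxon_id}.fasta"), "w") as fh:
            for cid, seq in g.contigs.items():
                fh.write(f">{cid}\n{seq}\n")
        with open(os.path.join(outdir, f"{g.taxon_id}.gff3"), "w") as fh:
            fh.write("##gff-version 3\n")
            for f in g.features:
                fh.write(
                    f"{f.contig_id}\tsim\t{f.kind}\t{f.start + 1}\t{f.end}\t.\t"
                    f"{f.strand}\t.\tID={f.feature_id};locus_tag={f.feature_id}\n"
                )
    with open(os.path.join(outdir, "orthologs.tsv"), "w") as fh:
        fh.write("ortholog_id\ttaxon_id\tfeature_id\n")
        for (taxon, fid), oid in sorted(ortholog_map.items()):
            fh.write(f"{oid}\t{taxon}\t{fid}\n")
    payload = {
        "elements": {
            key: [
                {
                    "element_id": e.element_id,
                    "element_type": e.element_type,
                    "sequence": e.sequence,
                    "per_taxon": {t: list(v) for t, v in e.per_taxon.items()},
                }
                for e in elems
            ]
            for key, elems in truth.elements.items()
        },
        "events": [list(e) for e in truth.events],
    }
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(payload, fh, indent=1)
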