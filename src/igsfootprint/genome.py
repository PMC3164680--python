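"""Annotated-genome model: features, intergenic spacers and cross-taxon orthology.

An intergenic spacer (IGS) is the stretch of sequence between two consecutive
annotated features on a contig.  In genomes with fully conserved gene order —
the situation in long-term obligate endosymbionts — a spacer can be matched
across taxa purely by the ortholog identities of its two flanking genes, which
is what makes phylogenetic footprinting of spacers possible at divergences
where the spacer sequences themselves are barely alignable.

Coordinates are 0-based half-open throughout; GFF3 input/output converts
to and from the 1-based closed convention of that format.
"""

from __future__ import annotations

import os
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

FEATURE_KINDS = ("CDS", "pseudogene", "rRNA", "tRNA", "ncRNA")
ORIENTATIONS = ("tandem", "convergent", "divergent")


class GenomeFormatError(ValueError):
    """Raised when an input file cannot be parsed."""


class ValidationError(ValueError):
    """Raised when parsed content violates a model invariant."""


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene-like feature on a contig."""

    feature_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    kind: str
    ortholog_id: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValidationError(f"unknown feature kind {self.kind!r}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"invalid strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"feature {self.feature_id}: bad span [{self.start},{self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeAnnotation:
    """Contig sequences plus an ordered feature list for one taxon."""

    taxon_id: str
    contigs: dict[str, str]
    features: list[GeneFeature]
    circular: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for f in self.features:
            if f.contig_id not in self.contigs:
                raise ValidationError(
                    f"feature {f.feature_id} on unknown contig {f.contig_id}"
                )
            if f.end > len(self.contigs[f.contig_id]):
                raise ValidationError(
                    f"feature {f.feature_id} extends beyond contig "
                    f"{f.contig_id} ({f.end} > {len(self.contigs[f.contig_id])})"
                )
        self.features.sort(key=lambda f: (f.contig_id, f.start, f.end))

    @property
    def gc_content(self) -> float:
        g = c = a = t = 0
        for seq in self.contigs.values():
            g += seq.count("G")
            c += seq.count("C")
            a += seq.count("A")
            t += seq.count("T")
        denom = a + c + g + t
        return (g + c) / denom if denom else 0.0

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def features_on(self, contig_id: str) -> list[GeneFeature]:
        return [f for f in self.features if f.contig_id == contig_id]


@dataclass
class IGSRecord:
    """One spacer between consecutive features, on the forward strand."""

    taxon_id: str
    contig_id: str
    start: int
    end: int
    left_gene: str
    right_gene: str
    orientation: str
    sequence: str
    left_strand: str = "+"
    right_strand: str = "+"
    excluded: bool = False  # overlap between flanking genes

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class OrthologousIGS:
    """Spacers from several taxa sharing the same flanking-ortholog pair."""

    key: tuple[str, str]
    members: dict[str, IGSRecord]
    orientation: str

    @property
    def n_taxa(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# parsing


def _kind_from_gb(feature) -> str | None:
    t = feature.type
    if t == "CDS":
        if "pseudo" in feature.qualifiers or "pseudogene" in feature.qualifiers:
            return "pseudogene"
        return "CDS"
    if t in ("rRNA", "tRNA", "ncRNA"):
        return t
    if t == "gene" and (
        "pseudo" in feature.qualifiers or "pseudogene" in feature.qualifiers
    ):
        return "pseudogene"
    return None


def read_genome(
    path: str,
    gff_path: str | None = None,
    taxon_id: str | None = None,
) -> GenomeAnnotation:
    """Read a GenBank flat file, or a FASTA plus GFF3 pair, into a genome model.

    ``path`` is either a GenBank file (``gff_path`` omitted) or a FASTA file
    accompanied by a GFF3 annotation in ``gff_path``.  Sequences are
    upper-cased; IUPAC ambiguity codes are preserved.
    """
    if gff_path is None:
        return _read_genbank(path, taxon_id)
    return _read_fasta_gff(path, gff_path, taxon_id)


def _read_genbank(path: str, taxon_id: str | None) -> GenomeAnnotation:
    from Bio import SeqIO

    contigs: dict[str, str] = {}
    features: list[GeneFeature] = []
    circular: set[str] = set()
    try:
        records = list(SeqIO.parse(path, "genbank"))
    except Exception as exc:  # Bio raises assorted types on malformed input
        raise GenomeFormatError(f"cannot parse GenBank file {path}: {exc}") from exc
    if not records:
        raise GenomeFormatError(f"no records in GenBank file {path}")
    for rec in records:
        contigs[rec.id] = str(rec.seq).upper()
        if rec.annotations.get("topology") == "circular":
            circular.add(rec.id)
        seen_pseudo_spans = set()
        for feat in rec.features:
            kind = _kind_from_gb(feat)
            if kind is None:
                continue
            span = (int(feat.location.start), int(feat.location.end), kind)
            if span in seen_pseudo_spans:
                continue
            seen_pseudo_spans.add(span)
            quals = feat.qualifiers
            fid = (
                quals.get("locus_tag", [None])[0]
                or quals.get("gene", [None])[0]
                or f"{rec.id}_{int(feat.location.start)}"
            )
            features.append(
                GeneFeature(
                    feature_id=fid,
                    contig_id=rec.id,
                    start=int(feat.location.start),
                    end=int(feat.location.end),
                    strand="+" if feat.location.strand != -1 else "-",
                    kind=kind,
                )
            )
    tax = taxon_id or os.path.splitext(os.path.basename(path))[0]
    return GenomeAnnotation(tax, contigs, features, circular)


_GFF_KIND = {
    "CDS": "CDS",
    "pseudogene": "pseudogene",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "ncRNA": "ncRNA",
}


def _read_fasta_gff(fasta: str, gff: str, taxon_id: str | None) -> GenomeAnnotation:
    import gffutils
    from Bio import SeqIO

    try:
        contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fasta, "fasta")}
    except ValueError as exc:
        raise GenomeFormatError(f"cannot parse FASTA file {fasta}: {exc}") from exc
    if not contigs:
        raise GenomeFormatError(f"no sequences in FASTA file {fasta}")
    try:
        db = gffutils.create_db(
            gff, ":memory:", merge_strategy="create_unique", keep_order=True
        )
    except Exception as exc:
        raise GenomeFormatError(f"cannot parse GFF3 file {gff}: {exc}") from exc
    features = []
    for feat in db.all_features():
        kind = _GFF_KIND.get(feat.featuretype)
        if kind is None:
            continue
        if feat.attributes.get("pseudo") or feat.attributes.get("pseudogene"):
            kind = "pseudogene"
        fid = (
            feat.attributes.get("locus_tag", [None])[0]
            or feat.attributes.get("ID", [None])[0]
            or f"{feat.seqid}_{feat.start - 1}"
        )
        features.append(
            GeneFeature(
                feature_id=fid,
                contig_id=feat.seqid,
                start=feat.start - 1,  # GFF3 is 1-based closed
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
                kind=kind,
            )
        )
    tax = taxon_id or os.path.splitext(os.path.basename(fasta))[0]
    return GenomeAnnotation(tax, contigs, features)


def load_ortholog_map(path: str) -> dict[tuple[str, str], str]:
    """Read the ortholog map TSV (ortholog_id, taxon_id, feature_id).

    Returns a mapping (taxon_id, feature_id) -> ortholog_id.
    """
    mapping: dict[tuple[str, str], str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "ortholog_id" and i == 0:
                continue
            if len(parts) < 3:
                raise GenomeFormatError(f"{path}:{i + 1}: expected 3 columns")
            oid, tax, fid = parts[:3]
            mapping[(tax, fid)] = oid
    return mapping


def apply_ortholog_map(
    genome: GenomeAnnotation, mapping: Mapping[tuple[str, str], str]
) -> GenomeAnnotation:
    """Return a copy of ``genome`` with ortholog_ids filled from the map."""
    feats = [
        GeneFeature(
            f.feature_id,
            f.contig_id,
            f.start,
            f.end,
            f.strand,
            f.kind,
            mapping.get((genome.taxon_id, f.feature_id), f.ortholog_id),
        )
        for f in genome.features
    ]
    return GenomeAnnotation(genome.taxon_id, genome.contigs, feats, genome.circular)


# ---------------------------------------------------------------------------
# spacers


def classify_orientation(left_strand: str, right_strand: str) -> str:
    """Orientation category of a spacer from its flanking gene strands.

    Equal strands are *tandem*; (+,−) means both genes transcribe into the
    spacer (*convergent*); (−,+) means both transcribe away (*divergent*).
    """
    for s in (left_strand, right_strand):
        if s not in ("+", "-"):
            raise ValidationError(f"invalid strand symbol {s!r}")
    if left_strand == right_strand:
        return "tandem"
    if left_strand == "+":
        return "convergent"
    return "divergent"


def extract_igs(
    genome: GenomeAnnotation,
    include_pseudogenes: bool = True,
    kinds: Iterable[str] | None = None,
) -> list[IGSRecord]:
    """Extract one spacer per adjacent feature pair on every contig.

    ``include_pseudogenes=False`` drops pseudogenes from the delimiter set, so
    a spacer runs across any decaying gene remnants between its intact
    neighbours — the convention used for footprinting runs, where pseudogene
    DNA is treated as spacer content.

    Overlapping features produce a zero-length record flagged ``excluded``.
    """
    allowed = set(kinds) if kinds is not None else set(FEATURE_KINDS)
    if not include_pseudogenes:
        allowed.discard("pseudogene")
    out: list[IGSRecord] = []
    for contig_id, seq in genome.contigs.items():
        feats = [f for f in genome.features_on(contig_id) if f.kind in allowed]
        assert feats == sorted(feats, key=lambda f: (f.start, f.end)), (
            "features must be sorted"
        )
        pairs = list(zip(feats, feats[1:]))
        if contig_id in genome.circular and len(feats) >= 2:
            pairs.append((feats[-1], feats[0]))
        for left, right in pairs:
            wrap = right.start < left.end and right is feats[0] and len(pairs) > 1
            if wrap:
                start, end = left.end, len(seq) + right.start
                spacer = seq[left.end :] + seq[: right.start]
            else:
                start = left.end
                end = max(right.start, left.end)
                spacer = seq[start:end]
            out.append(
                IGSRecord(
                    taxon_id=genome.taxon_id,
                    contig_id=contig_id,
                    start=start,
                    end=end,
                    left_gene=left.feature_id,
                    right_gene=right.feature_id,
                    orientation=classify_orientation(left.strand, right.strand),
                    sequence=spacer,
                    left_strand=left.strand,
                    right_strand=right.strand,
                    excluded=right.start < left.end and not wrap,
                )
            )
    return out


def match_orthologous_igs(
    genomes: Sequence[GenomeAnnotation],
    min_taxa: int = 2,
    include_pseudogenes: bool = True,
    exclusion_log: list | None = None,
) -> list[OrthologousIGS]:
    """Match spacers across taxa by their flanking ortholog pair.

    Spacers are orthologous when flanked by the identical ordered ortholog
    pair (or its strand-consistent reversal).  A spacer whose flanking pair
    exists in fewer than ``min_taxa`` taxa — e.g. because a deletion merged
    two spacers in one lineage — is dropped, with the reason recorded in
    ``exclusion_log`` if given.
    """
    by_key: dict[tuple[str, str], dict[str, IGSRecord]] = defaultdict(dict)
    orient: dict[tuple[str, str], str] = {}
    for genome in genomes:
        seen_oids: set[str] = set()
        for f in genome.features:
            if f.ortholog_id is not None:
                if f.ortholog_id in seen_oids:
                    raise ValidationError(
                        f"duplicate ortholog_id {f.ortholog_id} in {genome.taxon_id}"
                    )
                seen_oids.add(f.ortholog_id)
        oid_of = {f.feature_id: f.ortholog_id for f in genome.features}
        for rec in extract_igs(genome, include_pseudogenes=include_pseudogenes):
            lo, ro = oid_of.get(rec.left_gene), oid_of.get(rec.right_gene)
            if lo is None or ro is None:
                if exclusion_log is not None:
                    exclusion_log.append(
                        (genome.taxon_id, rec.left_gene, rec.right_gene, "no_ortholog")
                    )
                continue
            key = (lo, ro) if (lo, ro) <= (ro, lo) else (ro, lo)
            by_key[key][genome.taxon_id] = rec
            orient.setdefault(key, rec.orientation)
    out = []
    for key, members in sorted(by_key.items()):
        if len(members) < min_taxa:
            if exclusion_log is not None:
                exclusion_log.append((key, "members", len(members), "below_min_taxa"))
            continue
        out.append(OrthologousIGS(key=key, members=members, orientation=orient[key]))
    return out


def filter_analyzable(
    sets: Sequence[OrthologousIGS],
    alignments: Mapping[tuple[str, str], "object"],
    min_alignment_length: int = 50,
    filter_log: list | None = None,
) -> list[OrthologousIGS]:
    """Keep spacer sets whose alignment is >= 50 columns with no empty member.

    ``alignments`` maps each set key to its MultipleAlignment.  Sets with any
    zero-length member (flanking genes overlap in some taxon) are excluded.
    """
    kept = []
    for s in sets:
        aln = alignments.get(s.key)
        if aln is None:
            if filter_log is not None:
                filter_log.append((s.key, "no_alignment"))
            continue
        if any(m.length <= 0 or m.excluded for m in s.members.values()):
            if filter_log is not None:
                filter_log.append((s.key, "zero_length_member"))
            continue
        if aln.n_columns < min_alignment_length:
            if filter_log is not None:
                filter_log.append((s.key, f"alignment_below_{min_alignment_length}"))
            continue
        kept.append(s)
    return kept


def summarize_genome(
    genome: GenomeAnnotation,
    pseudogene_mutations: Mapping[str, int] | None = None,
    homopolymeric: Mapping[str, bool] | None = None,
) -> dict:
    """Per-genome tallies: feature counts, mutation-class counts, G+C%.

    ``pseudogene_mutations`` maps feature_id -> inactivating-mutation count
    and ``homopolymeric`` flags frameshifts within mononucleotide runs, both
    as produced by the erosion module.
    """
    counts = {k: 0 for k in FEATURE_KINDS}
    for f in genome.features:
        counts[f.kind] += 1
    summary = {
        "taxon_id": genome.taxon_id,
        "genome_length": genome.total_length,
        "gc_percent": round(100.0 * genome.gc_content, 1),
        "CDS": counts["CDS"],
        "pseudogenes": counts["pseudogene"],
        "rRNA": counts["rRNA"],
        "tRNA": counts["tRNA"],
        "ncRNA": counts["ncRNA"],
    }
    if pseudogene_mutations is not None:
        classes = {"1 mutation": 0, "2 mutations": 0, ">=3 mutations": 0}
        for fid, n in pseudogene_mutations.items():
            if n <= 1:
                classes["1 mutation"] += 1
            elif n == 2:
                classes["2 mutations"] += 1
            else:
                classes[">=3 mutations"] += 1
        summary["mutation_classes"] = classes
    if homopolymeric is not None:
        summary["homopolymeric_frameshifts"] = sum(
            1 for v in homopolymeric.values() if v
        )
    return summary


def write_igs_table(records: Iterable[IGSRecord], path: str) -> None:
    """Write the spacer inventory as TSV."""
    cols = [
        "taxon_id",
        "contig_id",
        "start",
        "end",
        "left_gene",
        "right_gene",
        "orientation",
        "length",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            fh.write(
                f"{r.taxon_id}\t{r.contig_id}\t{r.start}\t{r.end}\t"
                f"{r.left_gene}\t{r.right_gene}\t{r.orientation}\t{r.length}\n"
            )


def write_igs_bed(records: Iterable[IGSRecord], path: str) -> None:
    """Write spacers as BED6 (name = left|right flanking genes)."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.contig_id}\t{r.start}\t{r.end}\t"
                f"{r.left_gene}|{r.right_gene}\t0\t+\n"
            )
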