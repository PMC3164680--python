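"""End-to-end orchestration of the footprinting analysis.

``run_footprint`` composes the stages — genome model, alignment, conserved
k-mer scan, shuffled null, element annotation, erosion — on either real
annotated genomes or the synthetic generator, writes every stage's table
plus a run manifest, and returns the in-memory results for programmatic
use.  Deterministic stages are pure functions of (inputs, config);
stochastic stages additionally of (seed, replicate index).
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from typing import Mapping

import dendropy

from . import align as _align
from . import conservation as _cons
from . import elements as _elem
from . import erosion as _ero
from . import genome as _gen
from . import nullmodel as _null
from . import simulate as _sim

DEFAULTS = {
    "min_k": 5,
    "coverage_min_k": 6,
    "block_max_gap": 30,
    "block_single_min": 10,
    "min_alignment_length": 50,
    "min_taxa": 2,
    "spacers_ignore_pseudogenes": True,
    "null_replicates": 100,
    "null_mode": "row_residue_permutation",
    "structure_replicates": 100,
    "structure_alpha": 0.05,
    "structure_max_span": 200,
    "sd_window": (4, 20),
    "sd_max_mismatch": 1,
    "kaks_max_orthologs": 10,
    "seed": 0,
}


class PipelineError(RuntimeError):
    pass


def _validate_config(config: Mapping) -> dict:
    cfg = dict(DEFAULTS)
    cfg.update(config or {})
    if "tree" not in cfg and "simulate" not in cfg:
        raise PipelineError("config must provide 'tree' (newick) or 'simulate'")
    return cfg


def _prune_tree(tree: dendropy.Tree, labels: set[str]) -> dendropy.Tree:
    sub = tree.extract_tree_with_taxa_labels(labels)
    return sub


def run_footprint(
    config: Mapping,
    outdir: str | None = None,
    genomes=None,
    reference_srnas=None,
) -> dict:
    """Run the complete footprinting pipeline.

    ``config`` holds parameters (see ``DEFAULTS``) plus either
    ``simulate``: kwargs for the synthetic generator, or file inputs:
    ``genomes``: list of {"genbank": path} / {"fasta": p, "gff": p},
    ``ortholog_map``: TSV path, ``tree``: newick string or path.
    Pre-built ``genomes`` (GenomeAnnotation list) may be passed directly.
    """
    cfg = _validate_config(config)
    t0 = time.time()
    truth = None
    if genomes is None:
        if "simulate" in cfg:
            sim_kwargs = dict(cfg["simulate"])
            sc_fields = {f for f in _sim.SimulationConfig.__dataclass_fields__}
            sc = _sim.SimulationConfig(
                **{k: v for k, v in sim_kwargs.items() if k in sc_fields}
            )
            build_kwargs = {
                k: v for k, v in sim_kwargs.items() if k not in sc_fields
            }
            genomes, _omap, truth = _sim.build_synthetic_genomes(sc, **build_kwargs)
            tree = sc.tree()
        else:
            genomes = []
            for spec_ in cfg["genomes"]:
                if "genbank" in spec_:
                    g = _gen.read_genome(spec_["genbank"], taxon_id=spec_.get("taxon"))
                else:
                    g = _gen.read_genome(
                        spec_["fasta"], spec_["gff"], taxon_id=spec_.get("taxon")
                    )
                genomes.append(g)
            if "ortholog_map" in cfg:
                omap = _gen.load_ortholog_map(cfg["ortholog_map"])
                genomes = [_gen.apply_ortholog_map(g, omap) for g in genomes]
            tree = _read_tree(cfg["tree"])
    else:
        tree = _read_tree(cfg["tree"]) if "tree" in cfg else None
        if tree is None and "simulate" in cfg:
            tree = _sim.SimulationConfig(**cfg["simulate"]).tree()

    results: dict = {"config": cfg, "taxa": [g.taxon_id for g in genomes]}

    # --- spacers and orthology
    exclusions: list = []
    sets = _gen.match_orthologous_igs(
        genomes,
        min_taxa=cfg["min_taxa"],
        include_pseudogenes=not cfg["spacers_ignore_pseudogenes"],
        exclusion_log=exclusions,
    )
    results["n_orthologous_igs"] = len(sets)

    # --- alignment
    alignments: dict[tuple, _align.MultipleAlignment] = {}
    for s in sets:
        seqs = {t: r.sequence for t, r in s.members.items() if r.sequence}
        if len(seqs) < 2:
            continue
        guide = _prune_tree(tree, set(seqs)) if tree is not None else None
        alignments[s.key] = _align.align_set(
            seqs, guide_tree=guide, source_key="|".join(s.key)
        )
    filter_log: list = []
    analyzable = _gen.filter_analyzable(
        sets, alignments, cfg["min_alignment_length"], filter_log
    )
    results["n_analyzable"] = len(analyzable)
    results["orientation_counts"] = {
        o: sum(1 for s in analyzable if s.orientation == o)
        for o in _gen.ORIENTATIONS
    }

    # --- conservation
    keys = [s.key for s in analyzable]
    categories = {s.key: s.orientation for s in analyzable}
    aln_by_key = {k: alignments[k] for k in keys}
    kmers_by_key = {
        k: _cons.find_conserved_kmers(aln_by_key[k], min_k=cfg["min_k"])
        for k in keys
    }
    blocks_by_key = {
        k: _cons.group_into_blocks(
            v, cfg["block_max_gap"], cfg["block_single_min"]
        )
        for k, v in kmers_by_key.items()
    }
    summary = _cons.conservation_summary(
        aln_by_key, kmers_by_key, categories, cfg["coverage_min_k"]
    )
    results["conservation"] = summary

    # --- length correlations per orientation category
    correlations = {}
    taxa = sorted(results["taxa"])
    if len(taxa) >= 2:
        pair = (taxa[0], taxa[1])
        for orientation in _gen.ORIENTATIONS:
            pairs = [
                (s.members[pair[0]].length, s.members[pair[1]].length)
                for s in analyzable
                if s.orientation == orientation
                and pair[0] in s.members
                and pair[1] in s.members
            ]
            if len(pairs) >= 4:
                try:
                    c = _cons.length_correlation(
                        [a for a, _ in pairs], [b for _, b in pairs], pair
                    )
                    correlations[orientation] = {"n": c.n, "r": c.r, "z": c.fisher_z}
                except _cons.UndefinedCorrelation:
                    pass
    results["length_correlations"] = correlations

    # --- null model
    null_cfg = _null.ShuffleConfig(
        mode=cfg["null_mode"],
        replicates=cfg["null_replicates"],
        seed=cfg["seed"],
    )
    null = _null.null_kmer_distribution(aln_by_key, null_cfg, cfg["min_k"])
    results["null"] = {
        "mode": null_cfg.mode,
        "replicates": null_cfg.replicates,
        "mean_igs_with_kmer": null.mean_igs_with_kmer,
        "histogram_mean": null.histogram_mean,
    }

    # --- elements
    calls: list[_elem.ElementCall] = []
    for s in analyzable:
        aln = aln_by_key[s.key]
        any_member = next(iter(s.members.values()))
        if any_member.right_strand == "+":
            calls.extend(
                _elem.find_sd_sites(
                    aln, s.key, anchor="right+",
                    window=tuple(cfg["sd_window"]),
                    max_mismatch=cfg["sd_max_mismatch"],
                )
            )
        if any_member.left_strand == "-":
            calls.extend(
                _elem.find_sd_sites(
                    aln, s.key, anchor="left-",
                    window=tuple(cfg["sd_window"]),
                    max_mismatch=cfg["sd_max_mismatch"],
                )
            )
        calls.extend(_elem.find_terminators(aln, s.key))
        calls.extend(_elem.find_sigma32_sites(aln, s.key))
    if reference_srnas:
        calls.extend(
            _elem.match_known_srnas(analyzable, aln_by_key, reference_srnas)
        )
    # structural/bipartite elements must sit inside conserved sequence
    calls = _elem.restrict_to_conserved(calls, kmers_by_key)
    calls = _elem.dedupe_calls(calls)

    # structure test on spacers with a k-mer block and no prior element call
    called_keys = {c.igs_key for c in calls}
    structure_results: dict[tuple, _elem.StructureTestResult] = {}
    for i, s in enumerate(analyzable):
        if s.key in called_keys or not blocks_by_key[s.key]:
            continue
        lo = min(b.span[0] for b in blocks_by_key[s.key])
        hi = max(b.span[1] for b in blocks_by_key[s.key])
        hi = min(hi, lo + cfg["structure_max_span"])
        aln = aln_by_key[s.key]
        trimmed = _align.MultipleAlignment(
            source_key=aln.source_key,
            taxa=list(aln.taxa),
            rows=[r[lo:hi] for r in aln.rows],
            engine_tag=aln.engine_tag + "+trim",
        )
        structure_results[s.key] = _elem.structure_significance(
            trimmed,
            s.key,
            replicates=cfg["structure_replicates"],
            alpha=cfg["structure_alpha"],
            seed=cfg["seed"],
            igs_index=i,
        )
    collation = _elem.collate_elements(
        keys, kmers_by_key, blocks_by_key, calls, structure_results
    )
    results["elements"] = {
        "n_calls": len(calls),
        "counts_by_type": {
            t: sum(1 for c in calls if c.element_type == t)
            for t in _elem.ELEMENT_TYPES
        },
        "igs_with_sd": len({c.igs_key for c in calls if c.element_type == "SD"}),
        "n_structure_tested": len(structure_results),
        "n_structure_significant": sum(
            1 for r in structure_results.values() if r.significant
        ),
        "n_with_function": sum(1 for v in collation.values() if v["has_function"]),
        "classification_counts": _tally(
            v["classification"] for v in collation.values()
        ),
    }

    # --- erosion
    pseudo_calls: dict[tuple[str, str], object] = {}
    by_oid: dict[str, dict[str, tuple]] = {}
    for g in genomes:
        for f in g.features:
            if f.ortholog_id and f.kind in ("CDS", "pseudogene"):
                seq = g.contigs[f.contig_id][f.start : f.end]
                if f.strand == "-":
                    seq = _sim._revcomp(seq)
                by_oid.setdefault(f.ortholog_id, {})[g.taxon_id] = (f.kind, seq)
    for oid, members in sorted(by_oid.items()):
        ref = None
        for taxon, (kind, seq) in sorted(
            members.items(), key=lambda kv: -len(kv[1][1])
        ):
            if kind != "CDS":
                continue
            try:
                _ero._check_intact_reference(seq)
                ref = (taxon, seq)
                break
            except _ero.ErosionError:
                continue
        if ref is None:
            continue
        for taxon, (kind, seq) in sorted(members.items()):
            if taxon == ref[0]:
                continue
            call = _ero.call_pseudogene(seq, ref[1], oid, taxon)
            pseudo_calls[(oid, taxon)] = call
    matrix = _ero.build_state_matrix(genomes, pseudo_calls)
    event_map = _ero.map_events(matrix, tree) if tree is not None else None
    results["erosion"] = {
        "n_pseudogene_calls": sum(
            1
            for v in pseudo_calls.values()
            if isinstance(v, _ero.PseudogeneCall)
        ),
        "branch_events": event_map.branch_events if event_map else {},
        "total_events": event_map.total_events if event_map else 0,
    }

    # --- Ka/Ks on a sample of intact orthologs
    kaks = _pairwise_kaks(by_oid, cfg["kaks_max_orthologs"])
    results["kaks_mean"] = kaks

    if truth is not None:
        results["truth"] = {
            "n_planted_elements": sum(len(v) for v in truth.elements.values()),
            "events": list(truth.events),
        }
        results["elements_recovered"] = _score_recovery(truth, calls, analyzable)

    results["runtime_s"] = round(time.time() - t0, 2)
    if outdir:
        _write_outputs(
            outdir, cfg, results, analyzable, aln_by_key, kmers_by_key,
            blocks_by_key, calls, null, matrix, event_map,
        )
    results["_objects"] = {
        "sets": analyzable,
        "alignments": aln_by_key,
        "kmers": kmers_by_key,
        "blocks": blocks_by_key,
        "calls": calls,
        "structure": structure_results,
        "matrix": matrix,
        "event_map": event_map,
        "collation": collation,
        "truth": truth,
        "genomes": genomes,
        "pseudogene_calls": pseudo_calls,
    }
    return results


def _tally(items) -> dict:
    out: dict = {}
    for x in items:
        out[x] = out.get(x, 0) + 1
    return out


def _read_tree(tree_spec: str) -> dendropy.Tree:
    if os.path.exists(tree_spec):
        return dendropy.Tree.get(path=tree_spec, schema="newick")
    return dendropy.Tree.get(data=tree_spec, schema="newick")


def _pairwise_kaks(by_oid: Mapping, max_orthologs: int) -> dict:
    import numpy as np

    per_pair: dict[tuple[str, str], list[float]] = {}
    per_pair_ks: dict[tuple[str, str], list[float]] = {}
    n_done = 0
    for oid, members in sorted(by_oid.items()):
        intact = {}
        for taxon, (kind, seq) in sorted(members.items()):
            if kind != "CDS":
                continue
            try:
                _ero._check_intact_reference(seq)
            except _ero.ErosionError:
                continue
            intact[taxon] = seq
        if len(intact) < 2:
            continue
        try:
            aln = _align.align_cds_by_protein(intact, source_key=oid)
        except _align.AlignmentError:
            continue
        taxa = list(aln.taxa)
        for i, a in enumerate(taxa):
            for b in taxa[i + 1 :]:
                try:
                    est = _ero.estimate_ka_ks(
                        aln.row(a), aln.row(b), (a, b), oid
                    )
                except _ero.ErosionError:
                    continue
                per_pair.setdefault((a, b), []).append(est.ka)
                if not est.saturated:
                    per_pair_ks.setdefault((a, b), []).append(est.ks)
        n_done += 1
        if n_done >= max_orthologs:
            break
    out = {}
    for pair, kas in sorted(per_pair.items()):
        ks_list = per_pair_ks.get(pair, [])
        out["-".join(pair)] = {
            "ka": float(np.mean(kas)),
            "ks": float(np.mean(ks_list)) if ks_list else None,
            "n_genes": len(kas),
            "n_saturated": len(kas) - len(ks_list),
        }
    return out


def _score_recovery(truth, calls, analyzable) -> dict:
    """Compare element calls against the generator's planted truth."""
    planted = {
        (key, e.element_type)
        for key, elems in truth.elements.items()
        for e in elems
    }
    analyzable_keys = {"|".join(s.key) for s in analyzable}
    planted_vis = {
        (k, t) for (k, t) in planted
        if k in analyzable_keys and t in ("SD", "terminator")
    }
    called = {("|".join(c.igs_key), c.element_type) for c in calls}
    recovered = planted_vis & called
    return {
        "n_planted_in_analyzable": len(planted_vis),
        "n_recovered": len(recovered),
        "recall": len(recovered) / len(planted_vis) if planted_vis else None,
    }


def _write_outputs(
    outdir, cfg, results, analyzable, aln_by_key, kmers_by_key, blocks_by_key,
    calls, null, matrix, event_map,
) -> None:
    os.makedirs(outdir, exist_ok=True)
    all_kmers = [km for v in kmers_by_key.values() for km in v]
    _cons.write_kmer_table(all_kmers, os.path.join(outdir, "kmers.tsv"))
    with open(os.path.join(outdir, "blocks.tsv"), "w") as fh:
        fh.write("igs_key\tspan_start\tspan_end\tn_kmers\trule\n")
        for key, blocks in blocks_by_key.items():
            for b in blocks:
                fh.write(
                    f"{'|'.join(key)}\t{b.span[0]}\t{b.span[1]}\t"
                    f"{len(b.members)}\t{b.qualifying_rule}\n"
                )
    _elem.write_element_table(calls, os.path.join(outdir, "elements.tsv"))
    _null.write_null_histogram(null, os.path.join(outdir, "null_histogram.tsv"))
    _ero.write_state_matrix(matrix, os.path.join(outdir, "state_matrix.tsv"))
    if event_map:
        _ero.write_event_table(event_map, os.path.join(outdir, "events.tsv"))
    serializable = {
        k: v for k, v in results.items() if not k.startswith("_")
    }
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(serializable, fh, indent=1, default=str)
    manifest = {
        "config": {k: v for k, v in cfg.items()},
        "seed": cfg.get("seed"),
        "stage_counts": {
            "orthologous_igs": results["n_orthologous_igs"],
            "analyzable": results["n_analyzable"],
            "kmers": len(all_kmers),
            "element_calls": len(calls),
        },
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": sorted(os.listdir(outdir)),
    }
    blob = json.dumps(manifest, sort_keys=True, default=str).encode()
    manifest["manifest_sha256"] = hashlib.sha256(blob).hexdigest()
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)


def report_summary(run_dir: str) -> str:
    """Human-readable tallies from a completed run directory."""
    path = os.path.join(run_dir, "summary.json")
    if not os.path.exists(path):
        raise PipelineError(f"incomplete run: missing summary.json in {run_dir}")
    with open(path) as fh:
        s = json.load(fh)
    lines = [
        f"taxa: {', '.join(s['taxa'])}",
        f"orthologous spacer sets: {s['n_orthologous_igs']}",
        f"analyzable (>=50-column alignment): {s['n_analyzable']}",
        f"spacers with a conserved k-mer: {s['conservation']['n_igs_with_kmer']}",
        f"null expectation (mean spacers with a k-mer): "
        f"{s['null']['mean_igs_with_kmer']:.1f}",
        f"coverage by k-mers: {100 * s['conservation']['coverage_fraction']:.1f}%"
        f" ({s['conservation']['coverage_columns']}/"
        f"{s['conservation']['total_columns']} columns)",
        "element calls by type: "
        + ", ".join(
            f"{t}={n}" for t, n in s["elements"]["counts_by_type"].items() if n
        ),
        f"spacers with inferred function: {s['elements']['n_with_function']}",
    ]
    for cat, d in s["conservation"]["per_category"].items():
        lines.append(
            f"  {cat}: n={d['n_igs']} density={d['kmer_density_per_100nt']:.2f}"
            f"/100nt mean_len={d['mean_alignment_length']:.0f}"
            f" identity={d['mean_identity']:.3f}"
        )
    for ori, c in s.get("length_correlations", {}).items():
        lines.append(f"  length r ({ori}): {c['r']:.2f} (n={c['n']})")
    ev = s["erosion"]
    lines.append(f"erosion events: {ev['total_events']} on "
                 f"{len(ev['branch_events'])} branches")
    return "\n".join(lines)
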