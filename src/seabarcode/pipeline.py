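"""End-to-end orchestration: simulate (or load) → site composition →
barcoding gap → trees per method per locus combination → resolution →
diagnostic characters → inverted repeats → identification.

The pipeline is a pure function of (inputs, config, seed): every stage
consumes plain data structures, every random draw is seeded, and a rerun
writes byte-identical tables.  All method aggregates cover {NJ, MP, ML}
(or the configured subset) and are labelled with the method set used.
"""

from __future__ import annotations

import itertools
import json
import os
from dataclasses import dataclass, field

import pandas as pd

from . import caos, distances, identify, invrep, resolution, simdata, sitestats
from .seqio import build_supermatrix, write_newick
from .trees import SubstitutionModel, bootstrap_support


@dataclass
class PipelineConfig:
    methods: tuple = ("nj", "mp", "ml")
    bootstrap_reps: int = 100
    support_threshold: float = 50.0
    seed: int = 0
    combos: tuple | None = None       # default: singles + pairs + full combo
    gap_rank: str = "genus"
    spacer_loci: tuple = ("spacer-like",)
    guide_method: str = "nj"          # guide tree for CA discovery
    simulation: simdata.SimulationConfig = field(
        default_factory=simdata.SimulationConfig)
    ml_model: SubstitutionModel = field(
        default_factory=lambda: SubstitutionModel("JC69"))


def locus_combinations(loci) -> list[tuple[str, ...]]:
    loci = list(loci)
    combos = [(x,) for x in loci]
    combos += list(itertools.combinations(loci, 2))
    if len(loci) > 2:
        combos.append(tuple(loci))
    return combos


def combo_name(combo) -> str:
    return "+".join(combo)


def run_pipeline(config: PipelineConfig, alignments=None, metadata=None):
    """Run every stage; returns the report bundle (plain dict).

    With ``alignments``/``metadata`` given, those are analysed; otherwise
    a dataset is simulated from ``config.simulation`` at ``config.seed``.
    """
    if alignments is None:
        truth = simdata.simulate_dataset(config.simulation, seed=config.seed)
        alignments, metadata = truth.alignments, truth.metadata
    else:
        truth = None
    loci = list(alignments)
    combos = ([tuple(c) for c in config.combos] if config.combos
              else locus_combinations(loci))
    for c in combos:
        unknown = set(c) - set(loci)
        if unknown:
            raise ValueError(f"combination references unknown loci {unknown}")

    comp_reports = []
    gap_summaries = {}
    trees = {}
    res_reports = []
    for combo in combos:
        name = combo_name(combo)
        sm = build_supermatrix([alignments[x] for x in combo])
        aln = sm.as_alignment()
        comp_reports.append(sitestats.site_composition(aln, name=name))
        dm = distances.distance_matrix(aln)
        rep = distances.partition_distances(dm, metadata, rank=config.gap_rank)
        gap_summaries[name] = {
            "rank": rep.grouping_rank,
            "intra": rep.summaries["intra"],
            "inter": rep.summaries["inter"],
            "gap_stat": rep.gap_stat,
            "overlap_fraction": rep.overlap_fraction,
            "histogram": distances.gap_histogram(rep),
        }
        for m_idx, method in enumerate(config.methods):
            tree = bootstrap_support(
                aln, method=method, reps=config.bootstrap_reps,
                seed=config.seed * 10007 + m_idx * 101 + len(name),
                model=config.ml_model if method == "ml" else None)
            trees[(name, method)] = tree
            res_reports.append(resolution.species_resolution(
                tree, metadata, threshold=config.support_threshold,
                method=method, loci_combo=name))

    comp_table = sitestats.composition_table(comp_reports)
    pic_lookup = dict(zip(comp_table["locus_or_combo"], comp_table["pct_pic"]))
    aggregate = resolution.aggregate_methods(res_reports, pic_lookup=pic_lookup)

    # character-based diagnostics per single locus, species-level groups
    ca_tables = {}
    for locus in loci:
        aln = alignments[locus]
        grouping = caos.groups_from_metadata(aln, metadata, rank="species")
        ca_tables[locus] = caos.find_pure_cas(
            aln, grouping, grouping_source="species metadata")

    # inverted repeats on spacer-like loci
    ir_results = {}
    for locus in loci:
        if locus not in config.spacer_loci:
            continue
        aln = alignments[locus]
        hits = {r.id: invrep.find_inverted_repeats(r.seq) for r in aln.records}
        grouping = {r.id: r.genus for r in aln.records}
        ir_results[locus] = {
            "hits": hits,
            "conservation": invrep.ir_conservation(aln, hits, grouping),
        }

    # rank-level identification: leave-in self test against the library
    id_rows = []
    ref_locus = loci[0]
    library = {r.id: r.seq.replace("-", "") for r in alignments[ref_locus].records}
    for rid, seq in library.items():
        result = identify.identify_query(seq, library, metadata, query_id=rid)
        id_rows.append({"query": rid, "level": result.level,
                        "assigned": result.assigned_name,
                        "true_species": metadata[rid][0]})
    identification = pd.DataFrame(id_rows)

    return {
        "combos": [combo_name(c) for c in combos],
        "methods": list(config.methods),
        "composition": comp_table,
        "gap": gap_summaries,
        "trees": trees,
        "resolution": res_reports,
        "aggregate": aggregate,
        "ca_tables": ca_tables,
        "ir": ir_results,
        "identification": identification,
        "truth": truth,
        "config": config,
    }


def render_report(bundle, outdir) -> dict:
    """Write the bundle as TSV tables, Newick trees and a summary JSON.

    Returns the summary dict.  Missing stages are noted, not fatal.
    """
    os.makedirs(outdir, exist_ok=True)
    notes = []
    bundle["composition"].to_csv(
        os.path.join(outdir, "site_composition.tsv"), sep="\t", index=False)
    bundle["aggregate"].to_csv(
        os.path.join(outdir, "support_resolution.tsv"), sep="\t", index=False)

    ca_rows = []
    for locus, table in bundle.get("ca_tables", {}).items():
        counts = table.counts()
        if counts.empty:
            notes.append(f"no characteristic attributes found for {locus}")
            continue
        counts.insert(0, "locus", locus)
        ca_rows.append(counts)
    ca_df = (pd.concat(ca_rows, ignore_index=True) if ca_rows
             else pd.DataFrame(columns=["locus", "clade", "n_cas",
                                        "denominator", "label"]))
    ca_df.to_csv(os.path.join(outdir, "ca_counts.tsv"), sep="\t", index=False)

    hist_rows = []
    for combo, g in bundle["gap"].items():
        for which in ("intra", "inter"):
            for left, count in g["histogram"][which].items():
                hist_rows.append({"combo": combo, "set": which,
                                  "bin_left": left, "count": count})
    pd.DataFrame(hist_rows).to_csv(
        os.path.join(outdir, "gap_histogram.tsv"), sep="\t", index=False)

    tree_dir = os.path.join(outdir, "trees")
    os.makedirs(tree_dir, exist_ok=True)
    for (combo, method), tree in bundle["trees"].items():
        path = os.path.join(tree_dir, f"{combo.replace('+', '_')}.{method}.nwk")
        with open(path, "w") as fh:
            fh.write(write_newick(tree) + "\n")

    bundle["identification"].to_csv(
        os.path.join(outdir, "identification.tsv"), sep="\t", index=False)

    summary = {
        "combos": bundle["combos"],
        "methods": bundle["methods"],
        "method_set_note": "aggregates cover NJ/MP/ML; no Bayesian inference",
        "gap": {k: {kk: vv for kk, vv in v.items() if kk != "histogram"}
                for k, v in bundle["gap"].items()},
        "composition": bundle["composition"].to_dict(orient="records"),
        "aggregate": bundle["aggregate"].to_dict(orient="records"),
        "notes": notes,
    }
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
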