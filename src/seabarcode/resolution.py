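"""Species-resolution and branch-support statistics on inferred trees.

"Resolution" follows standard barcoding usage: a species is *resolved*
when its sequences form an exclusive clade (monophyly) whose most-recent
common ancestor carries support at or above a threshold (default 50%).
Singleton species (one sequence) cannot demonstrate exclusivity, so by
default they are excluded from the denominator; ``singleton_policy=
"count_if_supported"`` instead counts one as resolved when its terminal
branch hangs off a supported node.  "Average branch support" averages
internal-node supports over well-resolved nodes only (those at or above
the threshold).

Aggregates over methods (NJ / MP / ML here — Bayesian inference is not
part of this package, and every report says which method set it covers)
give the per-locus-combination mean and standard error tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqio import MetadataError
from .sitestats import DegenerateInputError
from .trees import leaf_labels, support_of

RANK_FIELD = {"species": 0, "genus": 1, "family": 2}


@dataclass
class ResolutionReport:
    method: str
    loci_combo: str
    threshold: float
    rows: pd.DataFrame                 # species, n_sequences, monophyletic, support, resolved, evaluable
    resolution_pct: float | None
    mean_support: float | None         # over internal nodes with support >= threshold
    method_set_note: str = "method set: NJ/MP/ML (no Bayesian inference)"


def _group_map(metadata, rank: str):
    idx = RANK_FIELD.get(rank, 0)

    def group_of(label):
        if label not in metadata:
            raise MetadataError(f"leaf {label!r} has no metadata")
        entry = metadata[label]
        return entry[idx] if isinstance(entry, tuple) else entry

    return group_of


def assess_monophyly(tree, metadata, taxon_rank: str = "species"):
    """Per-group (monophyletic?, clade support) for every group on the tree.

    The test is split-based and therefore independent of where the unrooted
    tree happens to be rooted: a multi-member group is monophyletic iff
    group-vs-rest is a bipartition of the tree, and its support is the
    support attached to that split.  A singleton group is monophyletic by
    convention, with the support of the node its terminal branch hangs from
    (0 when absent).
    """
    group_of = _group_map(metadata, taxon_rank)
    labels = leaf_labels(tree)
    groups: dict[str, set[str]] = {}
    for lb in labels:
        groups.setdefault(group_of(lb), set()).add(lb)

    # leaf set below every internal node, with that node's support; when the
    # same unrooted split appears twice (both children of a rooted root) the
    # exact-member node wins during lookup below
    below_map: dict[frozenset, float | None] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if below not in below_map or below_map[below] is None:
            below_map[below] = support_of(node)

    def lookup(members: frozenset):
        """Support of the split members-vs-rest, reading the exact node
        first and its unrooted complement second."""
        if members in below_map:
            return below_map[members]
        return below_map.get(frozenset(labels - members))

    out: dict[str, tuple[bool, float]] = {}
    n = len(labels)
    for name, members in groups.items():
        members = frozenset(members)
        supp = lookup(members)
        if len(members) in (1, n - 1, n):
            # a single leaf (or all-but-one, or all) is trivially exclusive
            out[name] = (True, supp if supp is not None else 0.0)
        elif supp is not None or frozenset(labels - members) in below_map \
                or members in below_map:
            out[name] = (True, supp if supp is not None else 0.0)
        else:
            out[name] = (False, 0.0)
    return out


def mean_supported(tree, threshold: float = 50.0) -> float | None:
    """Mean support over internal nodes with support >= threshold."""
    vals = [support_of(n) for n in tree.preorder_internal_node_iter()
            if support_of(n) is not None]
    kept = [v for v in vals if v >= threshold]
    return float(np.mean(kept)) if kept else None


def species_resolution(tree, metadata, threshold: float = 50.0,
                       singleton_policy: str = "exclude",
                       taxon_rank: str = "species",
                       method: str = "", loci_combo: str = "") -> ResolutionReport:
    """Resolution report for one tree (supports must be present on it)."""
    group_of = _group_map(metadata, taxon_rank)
    labels = leaf_labels(tree)
    sizes: dict[str, int] = {}
    for lb in labels:
        g = group_of(lb)
        sizes[g] = sizes.get(g, 0) + 1
    mono = assess_monophyly(tree, metadata, taxon_rank)

    rows = []
    for name in sorted(sizes):
        n = sizes[name]
        is_mono, supp = mono[name]
        if n >= 2:
            evaluable = True
            resolved = is_mono and supp >= threshold
        elif singleton_policy == "count_if_supported":
            evaluable = True
            resolved = supp >= threshold
        else:
            evaluable = False
            resolved = False
        rows.append({"species": name, "n_sequences": n,
                     "monophyletic": is_mono, "support": supp,
                     "resolved": resolved, "evaluable": evaluable})
    df = pd.DataFrame(rows)
    n_eval = int(df["evaluable"].sum())
    if n_eval == 0:
        raise DegenerateInputError(
            "no evaluable species (all singletons under policy 'exclude')")
    pct = 100.0 * df.loc[df["evaluable"], "resolved"].sum() / n_eval
    return ResolutionReport(
        method=method, loci_combo=loci_combo, threshold=threshold, rows=df,
        resolution_pct=float(pct), mean_support=mean_supported(tree, threshold),
    )


def aggregate_methods(reports, pic_lookup=None) -> pd.DataFrame:
    """Per-combination mean and standard error over methods.

    ``reports`` is an iterable of :class:`ResolutionReport`; SE is the
    sample standard deviation over methods divided by √n (0, flagged, when
    only one method contributed).  ``pic_lookup`` optionally maps a combo
    name to its PIC percentage for the PIC-vs-resolution table.
    """
    by_combo: dict[str, list[ResolutionReport]] = {}
    for rep in reports:
        by_combo.setdefault(rep.loci_combo, []).append(rep)

    def mean_se(vals):
        vals = [v for v in vals if v is not None]
        if not vals:
            return None, None, ""
        if len(vals) == 1:
            return float(vals[0]), 0.0, "single method; SE not estimable"
        return (float(np.mean(vals)),
                float(np.std(vals, ddof=1) / np.sqrt(len(vals))), "")

    rows = []
    for combo, reps in by_combo.items():
        ms, ms_se, note1 = mean_se([r.mean_support for r in reps])
        mr, mr_se, note2 = mean_se([r.resolution_pct for r in reps])
        row = {
            "loci_combo": combo,
            "methods": "/".join(r.method for r in reps),
            "mean_support": ms, "se_support": ms_se,
            "mean_resolution": mr, "se_resolution": mr_se,
            "note": note1 or note2,
        }
        if pic_lookup is not None:
            row["pct_pic"] = pic_lookup.get(combo)
        rows.append(row)
    return pd.DataFrame(rows)
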