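"""Character-based barcoding: diagnostic characteristic attributes (CAs).

A *pure simple* CA for a clade is an alignment column whose state is fixed
in every clade member that has a determinate character there, and absent
from every non-member.  Missing data are read permissively: a column where
the whole clade is missing yields no CA, and missing characters outside
the clade do not count as violations of absence (a strict mode treats any
outside missing character as potentially violating).

Gap characters can optionally act as diagnostic states (indel-borne
diagnostics in spacers); ``?`` and ambiguity codes never do.

Classification scores a query against each clade as (matched CAs) /
(clade's CAs); the query is assigned to the unique top scorer above a
floor, otherwise left unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .seqio import UNAMBIGUOUS, Alignment, AlignmentShapeError
from .trees import leaf_labels


class GroupingError(ValueError):
    pass


@dataclass(frozen=True)
class CharacteristicAttribute:
    clade_label: str
    position: int          # 1-based alignment column
    state: str
    category: str = "pure_simple"
    inside_count: int = 0
    outside_count: int = 0


@dataclass
class CATable:
    alignment_id: str
    grouping_source: str
    alignment_length: int      # the "/599"-style denominator
    attributes: list[CharacteristicAttribute]

    def by_clade(self) -> dict[str, list[CharacteristicAttribute]]:
        out: dict[str, list[CharacteristicAttribute]] = {}
        for ca in self.attributes:
            out.setdefault(ca.clade_label, []).append(ca)
        return out

    def counts(self) -> pd.DataFrame:
        by = self.by_clade()
        return pd.DataFrame(
            [{"clade": k, "n_cas": len(v),
              "denominator": self.alignment_length,
              "label": f"{len(v)}/{self.alignment_length}"}
             for k, v in sorted(by.items())])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"clade": ca.clade_label, "position": ca.position,
              "state": ca.state, "category": ca.category,
              "inside_count": ca.inside_count,
              "outside_count": ca.outside_count}
             for ca in self.attributes])


def find_pure_cas(alignment: Alignment, grouping: dict[str, set[str]],
                  gap_as_state: bool = False, strict_outside: bool = False,
                  grouping_source: str = "metadata") -> CATable:
    """Exhaustive column scan for pure simple CAs per group.

    ``grouping`` maps group labels to sets of record ids; groups may overlap
    (e.g. nested clades from a guide tree).  Each group must be non-empty.
    """
    diagnostic = set(UNAMBIGUOUS) | ({"-"} if gap_as_state else set())
    ids = alignment.ids()
    id_set = set(ids)
    for label, members in grouping.items():
        if not members:
            raise GroupingError(f"group {label!r} is empty")
        if not members <= id_set:
            raise GroupingError(
                f"group {label!r} has ids outside the alignment")
    seqs = {r.id: r.seq for r in alignment.records}
    attributes: list[CharacteristicAttribute] = []
    for label in grouping:
        members = grouping[label]
        outside = id_set - members
        for col in range(alignment.length):
            inside = [seqs[i][col] for i in members]
            inside_det = [c for c in inside if c in diagnostic]
            if not inside_det:
                continue  # whole group missing at this column
            states = set(inside_det)
            if len(states) != 1:
                continue
            state = states.pop()
            out_chars = [seqs[i][col] for i in outside]
            if strict_outside:
                violated = any(c == state or c not in diagnostic
                               for c in out_chars)
            else:
                violated = any(c == state for c in out_chars)
            if violated:
                continue
            attributes.append(CharacteristicAttribute(
                clade_label=label, position=col + 1, state=state,
                inside_count=len(inside_det),
                outside_count=sum(1 for c in out_chars if c == state)))
    return CATable(alignment_id=alignment.locus,
                   grouping_source=grouping_source,
                   alignment_length=alignment.length,
                   attributes=attributes)


def classify_by_cas(query_seq: str, ca_table: CATable, floor: float = 0.8):
    """Score an aligned query against every clade's CA set.

    Returns ``(scores, assignment)`` where ``scores`` maps clade labels to
    matched-fraction (``None`` for clades with zero CAs) and ``assignment``
    is the unique top scorer at or above the floor, else ``None``.
    """
    query = query_seq.upper()
    if len(query) != ca_table.alignment_length:
        raise AlignmentShapeError(
            f"query length {len(query)} != alignment length "
            f"{ca_table.alignment_length}")
    scores: dict[str, float | None] = {}
    for clade, cas in ca_table.by_clade().items():
        if not cas:
            scores[clade] = None
            continue
        matched = sum(1 for ca in cas if query[ca.position - 1] == ca.state)
        scores[clade] = matched / len(cas)
    defined = {c: s for c, s in scores.items() if s is not None}
    assignment = None
    if defined:
        top = max(defined.values())
        winners = [c for c, s in defined.items() if s == top]
        if len(winners) == 1 and top >= floor:
            assignment = winners[0]
    return scores, assignment


def groups_from_tree(guide_tree, alignment: Alignment,
                     min_size: int = 2) -> dict[str, set[str]]:
    """One group per internal node of the guide tree with >= min_size
    leaves (plus, at ``min_size=1``, every leaf as its own group).

    Labels come from node labels when present, otherwise are synthesised
    from the sorted member list.
    """
    tree_leaves = leaf_labels(guide_tree)
    if tree_leaves != set(alignment.ids()):
        raise GroupingError("guide-tree leaves do not match alignment rows")
    groups: dict[str, set[str]] = {}
    idx = 0
    for node in guide_tree.preorder_node_iter():
        if node is guide_tree.seed_node:
            continue
        members = {lf.taxon.label for lf in node.leaf_iter()}
        if len(members) < min_size or len(members) == len(tree_leaves):
            continue
        if node.is_leaf():
            label = node.taxon.label
        elif node.label and not node.label.replace(".", "").isdigit():
            label = node.label
        else:
            idx += 1
            label = f"clade_{idx}_" + "_".join(sorted(members)[:2])
        groups[label] = members
    return groups


def groups_from_metadata(alignment: Alignment, metadata,
                         rank: str = "species") -> dict[str, set[str]]:
    """Group alignment rows by a metadata rank (species/genus/family)."""
    idx = {"species": 0, "genus": 1, "family": 2}[rank]
    groups: dict[str, set[str]] = {}
    for rid in alignment.ids():
        entry = metadata[rid]
        key = entry[idx] if isinstance(entry, tuple) else entry
        groups.setdefault(key, set()).add(rid)
    return groups
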