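"""Multi-locus barcode-data simulator with known truth.

The generator emulates the sampling design of a regional barcoding study
of a small clade: a rank-structured, ultrametric taxonomy tree (families →
genera → species → individuals, with long family stems, shorter genus and
species stems, and very short terminal branches so conspecific individuals
are nearly identical — clonal, ramet-like sampling), and three plastid-
style loci evolved on that one shared tree with strongly unequal rates:
a slow rbcL-like coding locus, an intermediate matK-like locus, and a
fast trnH-psbA-like spacer with indels and an optional planted inverted
repeat.  Diagnostic columns (characteristic attributes) can be planted on
a designated clade for round-trip tests of character-based barcoding.

Because the simulator places every indel itself, it emits the *true*
alignment — no multiple-sequence-alignment step exists anywhere in the
pipeline.  Everything is bit-for-bit reproducible from (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .seqio import Alignment, SequenceRecord, parse_newick, reverse_complement
from .trees import SubstitutionModel


class ParameterError(ValueError):
    pass


@dataclass
class IRPlant:
    clade: str              # genus (or family) whose members carry the IR
    stem_length: int = 14
    loop_length: int = 20
    offset: int = 30        # alignment column (1-based) where the IR starts


@dataclass
class CAPlant:
    clade: str
    n_columns: int = 5


@dataclass
class LocusSpec:
    name: str
    length: int
    rate_multiplier: float = 1.0
    indel_rate: float = 0.0        # events per site per unit branch length
    indel_mean_length: float = 4.0
    ir_plant: IRPlant | None = None
    ca_plant: CAPlant | None = None

    def __post_init__(self) -> None:
        if self.rate_multiplier <= 0:
            raise ParameterError("rate multiplier must be > 0")
        if self.indel_rate < 0:
            raise ParameterError("indel rate must be >= 0")


@dataclass
class SimulationConfig:
    """Defaults give a seagrass-like design: 4 families, 10 genera,
    14 species, 2 individuals each; locus rates 1 : 3 : 8."""

    n_families: int = 4
    genera_per_family: tuple = (3, 3, 2, 2)
    species_per_genus: tuple = (2, 2, 1, 2, 1, 2, 1, 2, 1, 1)   # 15 species
    individuals_per_species: int = 2
    # node heights in expected substitutions/site at base (slow-locus) rate:
    # chosen so the slow locus stays mostly conserved, the intermediate locus
    # separates genera cleanly, and the fast spacer passes 20% inter-generic
    # p-distance without saturating
    root_height: float = 0.022
    family_height: float = 0.012
    genus_height: float = 0.005
    intraspecific_divergence: float = 0.0015  # expected divergence among conspecifics
    loci: tuple = ()
    model: SubstitutionModel = field(default_factory=lambda: SubstitutionModel("JC69"))
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.genera_per_family) != self.n_families:
            raise ParameterError("genera_per_family must list one count per family")
        n_genera = sum(self.genera_per_family)
        if len(self.species_per_genus) != n_genera:
            raise ParameterError("species_per_genus must list one count per genus")
        if sum(self.species_per_genus) == 0 or min(self.species_per_genus) < 1:
            raise ParameterError("every genus needs at least one species")
        if not self.loci:
            self.loci = default_loci()


def default_loci() -> tuple:
    return (
        LocusSpec("rbcL-like", length=599, rate_multiplier=1.0),
        LocusSpec("matK-like", length=845, rate_multiplier=3.0),
        LocusSpec("spacer-like", length=400, rate_multiplier=8.0,
                  indel_rate=0.05, indel_mean_length=4.0,
                  ir_plant=IRPlant(clade="GenusA", stem_length=14,
                                   loop_length=20, offset=40)),
    )


@dataclass
class TruthSet:
    tree_newick: str
    metadata: dict                      # id -> (species, genus, family, site)
    alignments: dict                    # locus name -> Alignment
    planted_irs: list = field(default_factory=list)
    planted_cas: list = field(default_factory=list)

    def registry_json(self) -> str:
        return json.dumps({
            "tree": self.tree_newick,
            "planted_irs": self.planted_irs,
            "planted_cas": self.planted_cas,
        }, indent=2)


# --------------------------------------------------------------------------

def sample_taxonomy_tree(config: SimulationConfig, seed: int | None = None):
    """Rank-structured ultrametric tree plus taxon metadata.

    Heights are fixed by the config (family stems longest, then genus,
    species, individual tips); the seed is reserved for future stochastic
    tree variants and currently only fixes label order, so the same config
    always yields the same Newick string.
    """
    del seed  # deterministic given config
    sp_height = config.intraspecific_divergence / 2.0
    if not (config.root_height > config.family_height > config.genus_height
            > sp_height >= 0):
        raise ParameterError("heights must decrease root > family > genus > species")
    metadata = {}

    def clade(parts, crown):
        """parts: [(fragment, height_above_tips)] -> (fragment, height).
        A singleton passes through (no degree-2 node), keeping the tree
        ultrametric with crown nodes exactly at the rank heights."""
        if len(parts) == 1:
            return parts[0]
        inner = ",".join(f"{frag}:{crown - h:.10g}" for frag, h in parts)
        return f"({inner})", crown

    fam_parts = []
    g_idx = 0
    genus_letters = [chr(ord("A") + i) for i in range(26)]
    for f in range(config.n_families):
        family = f"Family{f + 1}"
        gen_parts = []
        for _g in range(config.genera_per_family[f]):
            genus = f"Genus{genus_letters[g_idx]}"
            n_sp = config.species_per_genus[g_idx]
            g_idx += 1
            sp_parts = []
            for s in range(n_sp):
                species = f"{genus} sp{s + 1}"
                tips = []
                for i in range(config.individuals_per_species):
                    tid = f"{genus[5:]}{s + 1}i{i + 1}"
                    site = "SiteA" if i % 2 == 0 else "SiteB"
                    metadata[tid] = (species, genus, family, site)
                    tips.append((tid, 0.0))
                sp_parts.append(clade(tips, sp_height))
            gen_parts.append(clade(sp_parts, config.genus_height))
        fam_parts.append(clade(gen_parts, config.family_height))
    frag, _ = clade(fam_parts, config.root_height)
    newick = (frag if frag.startswith("(") else f"({frag})") + ";"
    return parse_newick(newick), metadata


# --------------------------------------------------------------------------

def _draw_states(rng, probs_rows: np.ndarray) -> np.ndarray:
    """Draw one categorical outcome per row of a (n, 4) probability array."""
    cum = probs_rows.cumsum(axis=1)
    u = rng.random(probs_rows.shape[0])[:, None]
    return (u > cum).sum(axis=1)


def evolve_locus(tree, locus: LocusSpec, model: SubstitutionModel,
                 seed: int, metadata=None) -> tuple[Alignment, dict]:
    """Evolve one locus along the tree; returns the true alignment and a
    registry of planted features.

    Substitutions follow the model's transition probabilities with branch
    lengths scaled by the locus rate multiplier.  Indels are Poisson events
    with geometric lengths; deletions blank columns in the descendant
    lineage, insertions add columns (gap-filled elsewhere), so the emitted
    alignment is exact by construction.  Planted IRs/CAs overwrite the
    designated clade's rows after evolution and are recorded.
    """
    rng = np.random.default_rng(seed)
    pi = np.asarray(model.freqs)
    L = locus.length
    if locus.ir_plant is not None:
        need = locus.ir_plant.offset + 2 * locus.ir_plant.stem_length \
            + locus.ir_plant.loop_length
        if need > L:
            raise ParameterError(
                f"planted IR needs {need} columns, locus has {L}")

    # sequences carry sortable float keys so insertions keep their place
    root_states = rng.choice(4, size=L, p=pi)
    root_keys = np.arange(L, dtype=float)

    tip_seqs: dict[str, dict[float, int]] = {}

    def evolve_branch(states, keys, t):
        if t > 0:
            p = model.transition_matrices(t)[0]
            states = _draw_states(rng, p[states])
        states = states.copy()
        keys = keys.copy()
        if locus.indel_rate > 0 and t > 0:
            n_events = rng.poisson(locus.indel_rate * len(states) * t)
            for _ in range(n_events):
                if len(states) < 4:
                    break
                ln = min(1 + rng.geometric(1.0 / locus.indel_mean_length),
                         max(1, len(states) // 4))
                pos = rng.integers(0, len(states))
                if rng.random() < 0.5:     # deletion
                    states = np.delete(states, slice(pos, pos + ln))
                    keys = np.delete(keys, slice(pos, pos + ln))
                else:                       # insertion
                    new_states = rng.choice(4, size=ln, p=pi)
                    lo = keys[pos - 1] if pos > 0 else keys[0] - 1.0
                    hi = keys[pos] if pos < len(keys) else keys[-1] + 1.0
                    new_keys = lo + (hi - lo) * (np.arange(1, ln + 1) / (ln + 1))
                    states = np.insert(states, pos, new_states)
                    keys = np.insert(keys, pos, new_keys)
        return states, keys

    def walk(node, states, keys):
        for child in node.child_nodes():
            t = (child.edge.length or 0.0) * locus.rate_multiplier
            st, ks = evolve_branch(states, keys, t)
            if child.is_leaf():
                tip_seqs[child.taxon.label] = dict(zip(ks.tolist(), st.tolist()))
            else:
                walk(child, st, ks)

    walk(tree.seed_node, root_states, root_keys)

    all_keys = sorted(set().union(*[set(s) for s in tip_seqs.values()]))
    key_col = {k: i for i, k in enumerate(all_keys)}
    bases = "ACGT"
    rows = {}
    for tid, seq in tip_seqs.items():
        row = ["-"] * len(all_keys)
        for k, st in seq.items():
            row[key_col[k]] = bases[st]
        rows[tid] = row

    registry = {"planted_irs": [], "planted_cas": []}
    meta = metadata or {}

    def clade_members(label):
        return [tid for tid, entry in meta.items()
                if label in (entry[1], entry[2], entry[0])]

    if locus.ir_plant is not None:
        irp = locus.ir_plant
        members = clade_members(irp.clade)
        if not members:
            raise ParameterError(f"IR clade {irp.clade!r} has no members")
        stem_raw = rng.choice(list("ACG"), size=irp.stem_length)
        stem = "".join(stem_raw)
        loop = "".join(rng.choice(list("ACGT"), size=irp.loop_length))
        insert = stem + loop + reverse_complement(stem)
        start_col = key_col.get(float(irp.offset), irp.offset)
        per_member_cols = {}
        for tid in members:
            # overwrite the member's first len(insert) non-gap columns at or
            # after the offset so the stem is contiguous in the ungapped row
            cols = [c for c in range(start_col, len(all_keys))
                    if rows[tid][c] != "-"][:len(insert)]
            if len(cols) < len(insert):
                raise ParameterError(
                    f"row {tid!r} too short to carry the planted IR")
            for c, ch in zip(cols, insert):
                rows[tid][c] = ch
            per_member_cols[tid] = [c + 1 for c in cols]
        registry["planted_irs"].append({
            "locus": locus.name, "clade": irp.clade,
            "stem_length": irp.stem_length, "loop_length": irp.loop_length,
            "stem": stem, "columns_per_member": per_member_cols})

    if locus.ca_plant is not None:
        cap = locus.ca_plant
        members = set(clade_members(cap.clade))
        if not members:
            raise ParameterError(f"CA clade {cap.clade!r} has no members")
        # fix a state inside the clade, a different one outside
        avail = [c for c in range(len(all_keys))
                 if all(rows[t][c] != "-" for t in rows)]
        chosen = rng.choice(avail, size=cap.n_columns, replace=False)
        for c in sorted(chosen.tolist()):
            inside, outside = "G", "A"
            for tid in rows:
                rows[tid][c] = inside if tid in members else outside
            registry["planted_cas"].append({
                "locus": locus.name, "clade": cap.clade,
                "column": c + 1, "state": inside})

    records = []
    for tid in sorted(rows):
        species, genus, family, site = meta.get(tid, ("", "", "", ""))
        records.append(SequenceRecord(
            id=tid, seq="".join(rows[tid]), species=species, genus=genus,
            family=family, site=site, locus=locus.name))
    return Alignment(locus=locus.name, records=records), registry


def simulate_dataset(config: SimulationConfig,
                     seed: int | None = None) -> TruthSet:
    """Simulate all configured loci on one shared taxonomy tree."""
    seed = config.seed if seed is None else seed
    tree, metadata = sample_taxonomy_tree(config)
    alignments = {}
    planted_irs, planted_cas = [], []
    for k, locus in enumerate(config.loci):
        aln, registry = evolve_locus(tree, locus, config.model,
                                     seed=seed * 1009 + k + 1,
                                     metadata=metadata)
        alignments[locus.name] = aln
        planted_irs += registry["planted_irs"]
        planted_cas += registry["planted_cas"]
    from .seqio import write_newick
    return TruthSet(tree_newick=write_newick(tree), metadata=metadata,
                    alignments=alignments, planted_irs=planted_irs,
                    planted_cas=planted_cas)


def write_dataset(truth: TruthSet, outdir) -> None:
    """Write per-locus FASTA, metadata TSV, truth Newick and the registry."""
    import os

    from .seqio import write_fasta, write_taxon_table
    os.makedirs(outdir, exist_ok=True)
    for name, aln in truth.alignments.items():
        write_fasta(aln, os.path.join(outdir, f"{name}.fasta"))
    any_aln = next(iter(truth.alignments.values()))
    write_taxon_table(any_aln.records, os.path.join(outdir, "taxa.tsv"))
    with open(os.path.join(outdir, "true_tree.nwk"), "w") as fh:
        fh.write(truth.tree_newick + "\n")
    with open(os.path.join(outdir, "truth_registry.json"), "w") as fh:
        fh.write(truth.registry_json())
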