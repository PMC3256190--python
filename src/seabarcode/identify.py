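"""In-silico PCR with degenerate primers and rank-level identification.

Primer matching expands IUPAC ambiguity codes position-wise: a primer
binds where every position's IUPAC set contains the template base, with up
to ``max_mismatches`` violations; both strands are scanned.  Amplicons are
all convergent forward/reverse binding combinations within a product-size
cap, product length inclusive of both primers.

Identification searches a *local* reference library by scored local
alignment (percent identity and query coverage) and assigns a rank level —
S (species), G (genus), F (family), O/unassigned — from the agreement of
the top hits, emulating a first-five-BLAST-hits reading without BLAST
statistics.  The rank thresholds are configurable surrogates, flagged in
the output, not doctrine.

The bundled primer set (:data:`SEAGRASS_PRIMERS`) covers the published
seagrass barcoding pairs: P609/P610 (rbcL, 599-bp fragment), P607/P608 and
P646/P647 (matK, 889 / 945 bp), P672/P673 (rps16-trnQ), P674/P675 (ITS)
and P676/P677 (trnH-psbA spacer, 296–415 bp).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import Align

from .seqio import IUPAC, reverse_complement


class InputError(ValueError):
    pass


@dataclass
class PrimerPair:
    name: str
    forward: str
    reverse: str            # 5'->3' on the opposite strand, per convention
    product_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.forward = self.forward.upper()
        self.reverse = self.reverse.upper()
        for p in (self.forward, self.reverse):
            if len(p) < 10:
                raise InputError(f"primer {p!r} shorter than 10 nt")
            bad = [c for c in p if c not in IUPAC]
            if bad:
                raise InputError(f"primer {p!r}: non-IUPAC characters {bad}")


SEAGRASS_PRIMERS = [
    PrimerPair("P609/P610-rbcL", "GTAAAATCAAGTCCACCRCG",
               "ATGTCACCACAAACAGAGACTAAAGC", (599, 599)),
    PrimerPair("P607/P608-matK", "CGTACAGTACTTTTGTGTTTACGAG",
               "ACCCAGTCCATCTGGAAATCTTGGTTC", (889, 889)),
    PrimerPair("P646/P647-matK", "TAATTTACGATCAATTCATTC",
               "GTTCTAGCACAAGAAAGTCG", (945, 945)),
    PrimerPair("P672/P673-rps16-trnQ", "GCGTGGCCAAGYGGTAAGGC",
               "GTTGCTTTYTACCACATCGTTT", (850, 1400)),
    PrimerPair("P674/P675-ITS", "CCTTATCATTTAGAGGAAGGAG",
               "TCCTCCGCTTATTGATATGC", (900, 1800)),
    PrimerPair("P676/P677-trnH-psbA", "GTTATGCATGAACGTAATGCTC",
               "CGCGCATGGTGGATTCACAATCC", (296, 415)),
]


@dataclass
class Binding:
    start: int        # 1-based on the plus strand of the template
    end: int
    strand: str       # '+' primer as given matches plus strand; '-' matches minus
    mismatches: int


@dataclass
class AmpliconPrediction:
    template_id: str
    forward: Binding
    reverse: Binding
    product_length: int
    mismatches: int


@dataclass
class IdentificationResult:
    query_id: str
    hits: pd.DataFrame          # reference_id, identity, coverage + metadata
    level: str                  # S | G | F | O | unassigned
    assigned_name: str | None
    thresholds: dict = field(default_factory=dict)


def _matches(primer_char: str, template_char: str) -> bool:
    return template_char in IUPAC.get(primer_char, "")


def match_primer(template: str, primer: str,
                 max_mismatches: int = 0) -> list[Binding]:
    """All binding sites of a degenerate primer on both template strands."""
    template = template.upper()
    primer = primer.upper()
    n, m = len(template), len(primer)
    out: list[Binding] = []
    if m > n:
        return out
    for strand, tpl in (("+", template), ("-", reverse_complement(template))):
        for i in range(n - m + 1):
            mm = 0
            for k in range(m):
                if not _matches(primer[k], tpl[i + k]):
                    mm += 1
                    if mm > max_mismatches:
                        break
            else:
                if strand == "+":
                    out.append(Binding(i + 1, i + m, "+", mm))
                else:
                    out.append(Binding(n - (i + m) + 1, n - i, "-", mm))
    return out


def insilico_pcr(template: str, pair: PrimerPair, template_id: str = "",
                 max_mismatches: int = 0,
                 max_product: int = 5000) -> list[AmpliconPrediction]:
    """All convergent amplicons of a primer pair on a template.

    A product needs the forward primer bound on one strand and the reverse
    primer bound downstream on the other; length is inclusive of both
    primer footprints.
    """
    fwd = match_primer(template, pair.forward, max_mismatches)
    rev = match_primer(template, pair.reverse, max_mismatches)
    out = []
    for f in fwd:
        for r in rev:
            if f.strand == "+" and r.strand == "-" and r.end > f.start:
                length = r.end - f.start + 1
            elif f.strand == "-" and r.strand == "+" and f.end > r.start:
                length = f.end - r.start + 1
            else:
                continue
            if length <= max_product and length > 0:
                out.append(AmpliconPrediction(
                    template_id=template_id, forward=f, reverse=r,
                    product_length=length,
                    mismatches=f.mismatches + r.mismatches))
    out.sort(key=lambda a: (a.product_length, a.forward.start))
    return out


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = 1
    al.mismatch_score = -1
    al.open_gap_score = -2
    al.extend_gap_score = -0.5
    return al


def align_identity(query: str, reference: str) -> tuple[float, float]:
    """Local-alignment percent identity and query coverage.

    Identity = matches / alignment columns (gap columns included);
    coverage = aligned query span / query length.  Both in percent.
    """
    query, reference = query.upper(), reference.upper()
    if not query or not reference:
        raise InputError("empty sequence")
    aln = _aligner().align(query, reference)[0]
    qa, ra = aln[0], aln[1]
    ncol = len(qa)
    matches = sum(1 for a, b in zip(qa, ra) if a == b and a != "-")
    qspan = aln.aligned[0][-1][1] - aln.aligned[0][0][0]
    return 100.0 * matches / ncol, 100.0 * qspan / len(query)


DEFAULT_THRESHOLDS = {"species": 99.0, "genus": 95.0, "family": 90.0,
                      "floor": 80.0, "band": 0.5}


def identify_query(query: str, reference_library, metadata,
                   query_id: str = "query", k: int = 5,
                   thresholds: dict | None = None) -> IdentificationResult:
    """Identify a query against a local reference library.

    ``reference_library`` is ``{reference_id: sequence}``; ``metadata`` maps
    each reference id to ``(species, genus, family, site)``.  The top ``k``
    hits by identity are retained; the level rule looks at the hits inside
    the top identity band (default 0.5 points): a single species at or
    above the species threshold gives S, a single genus at the genus
    threshold gives G, a single family at the family threshold gives F;
    anything above the floor is O, below it unassigned.
    """
    if not reference_library:
        raise InputError("empty reference library")
    th = dict(DEFAULT_THRESHOLDS, **(thresholds or {}))
    rows = []
    for rid, ref in reference_library.items():
        ident, cov = align_identity(query, ref)
        species, genus, family, _site = metadata[rid]
        rows.append({"reference_id": rid, "identity": ident,
                     "coverage": cov, "species": species,
                     "genus": genus, "family": family})
    hits = (pd.DataFrame(rows)
            .sort_values(["identity", "coverage"], ascending=False,
                         kind="stable")
            .head(k).reset_index(drop=True))
    top = hits.iloc[0]
    band = hits[hits["identity"] >= top["identity"] - th["band"]]
    level, name = "unassigned", None
    if top["identity"] >= th["floor"]:
        level, name = "O", None
        if band["family"].nunique() == 1 and top["identity"] >= th["family"]:
            level, name = "F", top["family"]
        if band["genus"].nunique() == 1 and top["identity"] >= th["genus"]:
            level, name = "G", top["genus"]
        if band["species"].nunique() == 1 and top["identity"] >= th["species"]:
            level, name = "S", top["species"]
    return IdentificationResult(query_id=query_id, hits=hits, level=level,
                                assigned_name=name, thresholds=th)
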