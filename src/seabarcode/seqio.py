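"""Sequence, alignment, tree and supermatrix data model plus readers/writers.

Conventions used throughout the package:

* sequences are stored uppercase over the IUPAC DNA alphabet plus ``-``
  (alignment gap) and ``?`` (missing data); ``U`` is normalised to ``T``;
* ``-`` and ``?`` are distinct on output: a gap is an inferred indel, a
  ``?`` marks data that was never observed (e.g. a locus not sequenced for
  a taxon in a supermatrix);
* all column coordinates reported to users are 1-based inclusive;
* trees are ``dendropy.Tree`` objects; bootstrap/consensus supports are
  carried as internal-node labels in percent.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import dendropy

#: IUPAC nucleotide codes -> set of unambiguous bases.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

ALPHABET = frozenset(IUPAC) | {"-", "?"}
UNAMBIGUOUS = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-?", "TGCAYRSWMKVHDBN-?")


def reverse_complement(seq: str) -> str:
    """Reverse complement preserving IUPAC ambiguity codes and gaps."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


class SeqFormatError(ValueError):
    """Malformed input: bad FASTA/Newick/TSV syntax or illegal characters."""


class AlignmentShapeError(ValueError):
    """Rows of an alignment (or a pairwise comparison) differ in length."""


class MetadataError(KeyError):
    """Missing, duplicated or inconsistent taxon metadata."""


class AmbiguityError(ValueError):
    """The same (taxon, locus) combination occurs more than once."""


@dataclass
class SequenceRecord:
    """One aligned sequence with its taxonomic labels.

    ``genus`` is always the first token of ``species``; the constructor
    derives it when not given.
    """

    id: str
    seq: str
    species: str = ""
    genus: str = ""
    family: str = ""
    site: str = ""
    locus: str = ""

    def __post_init__(self) -> None:
        s = self.seq.upper().replace("U", "T")
        if not s:
            raise SeqFormatError(f"record {self.id!r}: empty sequence")
        for pos, ch in enumerate(s, start=1):
            if ch not in ALPHABET:
                raise SeqFormatError(
                    f"record {self.id!r}: illegal character {ch!r} at position {pos}"
                )
        self.seq = s
        if self.species and not self.genus:
            self.genus = self.species.split()[0]
        if self.species and self.genus != self.species.split()[0]:
            raise MetadataError(
                f"record {self.id!r}: genus {self.genus!r} does not match "
                f"species {self.species!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Alignment:
    """An aligned set of records for one locus (equal-length rows, unique ids)."""

    locus: str
    records: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentShapeError("alignment needs at least one record")
        length = len(self.records[0])
        for rec in self.records:
            if len(rec) != length:
                raise AlignmentShapeError(
                    f"record {rec.id!r} has length {len(rec)}, expected {length}"
                )
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise MetadataError(f"duplicate record ids: {dup}")

    @property
    def length(self) -> int:
        return len(self.records[0])

    def __len__(self) -> int:
        return len(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def column(self, col: int) -> str:
        """Column characters (1-based column index)."""
        return "".join(r.seq[col - 1] for r in self.records)

    def get(self, rec_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == rec_id:
                return r
        raise MetadataError(f"no record {rec_id!r} in alignment {self.locus!r}")


@dataclass
class Supermatrix:
    """Column-wise concatenation of per-locus alignments over a shared taxon set.

    ``partitions`` holds (locus, start, end) spans, 1-based inclusive; a taxon
    absent from a locus carries ``?`` across that partition.
    """

    records: list[SequenceRecord]
    partitions: list[tuple[str, int, int]]
    missing_char: str = "?"

    @property
    def length(self) -> int:
        return self.partitions[-1][2]

    def as_alignment(self) -> Alignment:
        return Alignment(locus="+".join(p[0] for p in self.partitions),
                         records=self.records)


def _parse_header(header: str, locus: str) -> SequenceRecord:
    # Dialect: ">id" or ">id|species|genus|family|site" (trailing fields optional).
    parts = [p.strip() for p in header.split("|")]
    fields = dict(zip(["species", "genus", "family", "site"], parts[1:]))
    return SequenceRecord(id=parts[0], seq="A", locus=locus, **fields)


def read_fasta(path_or_text, locus: str = "") -> Alignment:
    """Read an aligned FASTA file (path, file object or raw text).

    Headers may carry metadata as ``id|species|genus|family|site``; plain
    ``>id`` headers are accepted and metadata can come from a taxon table
    instead (the table wins on conflict, see :func:`apply_taxon_table`).
    """
    if hasattr(path_or_text, "read"):
        text = path_or_text.read()
    else:
        text = str(path_or_text)
        if not text.lstrip().startswith(">"):
            with open(text) as fh:
                text = fh.read()
    records: list[SequenceRecord] = []
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        proto = _parse_header(header, locus)
        records.append(replace(proto, seq="".join(chunks)))

    for line in io.StringIO(text):
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header = line[1:].strip()
            chunks = []
        else:
            if header is None:
                raise SeqFormatError("sequence data before first FASTA header")
            chunks.append(line)
    flush()
    if not records:
        raise SeqFormatError("no FASTA records found")
    return Alignment(locus=locus, records=records)


def write_fasta(alignment: Alignment, path=None, with_metadata: bool = False) -> str:
    lines = []
    for rec in alignment.records:
        if with_metadata:
            lines.append(f">{rec.id}|{rec.species}|{rec.genus}|{rec.family}|{rec.site}")
        else:
            lines.append(f">{rec.id}")
        lines.append(rec.seq)
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_taxon_table(path_or_text) -> dict[str, tuple[str, str, str, str]]:
    """Read a TSV with header ``id  species  genus  family  site``.

    Returns ``{id: (species, genus, family, site)}``; genus is derived from
    the species binomial when the column is empty.
    """
    if hasattr(path_or_text, "read"):
        text = path_or_text.read()
    else:
        text = str(path_or_text)
        if "\t" not in text and "\n" not in text:
            with open(text) as fh:
                text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise SeqFormatError("empty taxon table")
    header = [h.strip().lower() for h in lines[0].split("\t")]
    required = ["id", "species", "genus", "family", "site"]
    idx = {}
    for col in required:
        if col not in header:
            raise SeqFormatError(f"taxon table missing column {col!r}")
        idx[col] = header.index(col)
    table: dict[str, tuple[str, str, str, str]] = {}
    for ln in lines[1:]:
        fields = ln.split("\t")
        fields += [""] * (len(header) - len(fields))
        rid = fields[idx["id"]].strip()
        if rid in table:
            raise MetadataError(f"duplicate id {rid!r} in taxon table")
        species = fields[idx["species"]].strip()
        genus = fields[idx["genus"]].strip() or (species.split()[0] if species else "")
        table[rid] = (species, genus, fields[idx["family"]].strip(),
                      fields[idx["site"]].strip())
    return table


def apply_taxon_table(alignment: Alignment, table, strict: bool = True) -> Alignment:
    """Attach metadata from a taxon table; the table overrides header metadata.

    With ``strict=False`` records absent from the table keep their header
    metadata (or empty placeholders).
    """
    new = []
    for rec in alignment.records:
        if rec.id in table:
            species, genus, family, site = table[rec.id]
            new.append(replace(rec, species=species, genus=genus,
                               family=family, site=site))
        elif strict:
            raise MetadataError(f"record {rec.id!r} not in taxon table")
        else:
            new.append(rec)
    return Alignment(locus=alignment.locus, records=new)


def write_taxon_table(records, path=None) -> str:
    lines = ["id\tspecies\tgenus\tfamily\tsite"]
    for rec in records:
        lines.append(f"{rec.id}\t{rec.species}\t{rec.genus}\t{rec.family}\t{rec.site}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# --- trees -----------------------------------------------------------------

def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string (or read a file path ending in .nwk/.tre/.newick).

    Internal-node labels are kept as labels; when numeric they are the
    support values (percent) this package writes.
    """
    if not text.lstrip().startswith("(") and text.strip().endswith((".nwk", ".tre", ".newick")):
        with open(text.strip()) as fh:
            text = fh.read()
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise SeqFormatError(f"Newick parse error: {exc}") from exc
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True).strip()


# --- supermatrix -----------------------------------------------------------

def default_taxon_key(rec: SequenceRecord) -> str:
    return rec.id


def build_supermatrix(alignments, taxon_key=default_taxon_key) -> Supermatrix:
    """Concatenate per-locus alignments into one partitioned matrix.

    Rows are the union of taxa across loci (first-seen order); a taxon
    missing from a locus gets ``?`` across that partition.  A duplicate
    (taxon, locus) pair raises :class:`AmbiguityError` — never a silent
    overwrite.
    """
    alignments = list(alignments)
    if not alignments:
        raise ValueError("need at least one alignment")
    taxa: list[str] = []
    meta: dict[str, SequenceRecord] = {}
    per_locus: list[dict[str, str]] = []
    for aln in alignments:
        rows: dict[str, str] = {}
        for rec in aln.records:
            key = taxon_key(rec)
            if key in rows:
                raise AmbiguityError(
                    f"taxon {key!r} appears twice in locus {aln.locus!r}")
            rows[key] = rec.seq
            if key not in meta:
                meta[key] = rec
                taxa.append(key)
        per_locus.append(rows)

    partitions: list[tuple[str, int, int]] = []
    start = 1
    for aln in alignments:
        end = start + aln.length - 1
        partitions.append((aln.locus, start, end))
        start = end + 1

    records = []
    for key in taxa:
        chunks = []
        for aln, rows in zip(alignments, per_locus):
            chunks.append(rows.get(key, "?" * aln.length))
        proto = meta[key]
        records.append(replace(proto, id=key, seq="".join(chunks),
                               locus="+".join(a.locus for a in alignments)))
    return Supermatrix(records=records, partitions=partitions)


def write_nexus(matrix: Supermatrix, path=None) -> str:
    """Export a supermatrix as a NEXUS file with a sets block of charsets."""
    n, length = len(matrix.records), matrix.length
    lines = [
        "#NEXUS", "BEGIN DATA;",
        f"  DIMENSIONS NTAX={n} NCHAR={length};",
        "  FORMAT DATATYPE=DNA GAP=- MISSING=?;",
        "  MATRIX",
    ]
    width = max(len(r.id) for r in matrix.records) + 2
    for rec in matrix.records:
        lines.append(f"    {rec.id.replace(' ', '_'):<{width}}{rec.seq}")
    lines += ["  ;", "END;", "BEGIN SETS;"]
    for locus, start, end in matrix.partitions:
        lines.append(f"  CHARSET {locus.replace('-', '_')} = {start}-{end};")
    lines += ["END;"]
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
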