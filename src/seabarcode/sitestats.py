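"""Alignment-column classification and per-locus site composition.

Columns are classified from the unambiguous bases (A/C/G/T) they contain;
gaps, ``?`` and IUPAC ambiguity codes are treated as missing.  A column is

* *indeterminate* when fewer than two comparable bases remain,
* *conserved* when all comparable bases agree,
* *variable* otherwise; a variable column is *parsimony-informative* (PIC)
  when at least two states each occur at least twice, and a *singleton*
  otherwise.

Percentages are reported on the non-indeterminate denominator so that
conserved + variable = 100% and singleton + PIC = variable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .seqio import UNAMBIGUOUS, Alignment, Supermatrix


class DegenerateInputError(ValueError):
    """Statistics requested on an input with too few rows."""


@dataclass
class SiteClass:
    column: int                  # 1-based
    n_comparable: int
    states: Counter
    label: str                   # conserved | variable | indeterminate
    sublabel: str | None = None  # singleton | parsimony_informative

    @property
    def is_pic(self) -> bool:
        return self.sublabel == "parsimony_informative"


@dataclass
class CompositionReport:
    locus_or_combo: str
    n_columns: int
    denominator: int             # non-indeterminate columns
    conserved: int
    variable: int
    singleton: int
    pic: int

    def _pct(self, x: int) -> float:
        return round(100.0 * x / self.denominator, 1) if self.denominator else 0.0

    @property
    def pct_conserved(self) -> float:
        return self._pct(self.conserved)

    @property
    def pct_variable(self) -> float:
        return self._pct(self.variable)

    @property
    def pct_singleton(self) -> float:
        return self._pct(self.singleton)

    @property
    def pct_pic(self) -> float:
        return self._pct(self.pic)


def classify_site(column_chars, column: int = 0,
                  gap_as_state: bool = False) -> SiteClass:
    """Classify one alignment column (one character per row).

    With ``gap_as_state=True`` the gap character ``-`` counts as a fifth
    state (sensitivity mode for indel-rich spacers); ``?`` and ambiguity
    codes are always missing.
    """
    comparable = set(UNAMBIGUOUS) | ({"-"} if gap_as_state else set())
    states = Counter(c for c in str(column_chars).upper() if c in comparable)
    n = sum(states.values())
    if n < 2:
        return SiteClass(column, n, states, "indeterminate")
    if len(states) == 1:
        return SiteClass(column, n, states, "conserved")
    n_repeated = sum(1 for c in states.values() if c >= 2)
    sub = "parsimony_informative" if n_repeated >= 2 else "singleton"
    return SiteClass(column, n, states, "variable", sub)


def classify_alignment(aln, gap_as_state: bool = False) -> list[SiteClass]:
    if isinstance(aln, Supermatrix):
        aln = aln.as_alignment()
    return [classify_site(aln.column(c), column=c, gap_as_state=gap_as_state)
            for c in range(1, aln.length + 1)]


def site_composition(aln, name: str | None = None,
                     gap_as_state: bool = False) -> CompositionReport:
    """Aggregate :func:`classify_site` over all columns of an alignment."""
    if isinstance(aln, Supermatrix):
        aln = aln.as_alignment()
    if len(aln) < 2:
        raise DegenerateInputError("site composition needs at least 2 rows")
    sites = classify_alignment(aln, gap_as_state=gap_as_state)
    conserved = sum(1 for s in sites if s.label == "conserved")
    singleton = sum(1 for s in sites if s.sublabel == "singleton")
    pic = sum(1 for s in sites if s.is_pic)
    variable = singleton + pic
    return CompositionReport(
        locus_or_combo=name or aln.locus,
        n_columns=len(sites),
        denominator=conserved + variable,
        conserved=conserved, variable=variable,
        singleton=singleton, pic=pic,
    )


def composition_table(reports, sort_by_pic: bool = False) -> pd.DataFrame:
    """One row per locus/combination; stable (input-order) tie handling."""
    rows = [{
        "locus_or_combo": r.locus_or_combo,
        "n_columns": r.n_columns,
        "denominator": r.denominator,
        "pct_conserved": r.pct_conserved,
        "pct_variable": r.pct_variable,
        "pct_singleton": r.pct_singleton,
        "pct_pic": r.pct_pic,
    } for r in reports]
    df = pd.DataFrame(rows)
    if sort_by_pic and not df.empty:
        df = df.sort_values("pct_pic", ascending=False, kind="stable")
        df = df.reset_index(drop=True)
    return df
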