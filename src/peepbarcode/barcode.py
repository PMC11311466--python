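"""Combinatorial expression barcodes.

The per-gene Up/Norm/Down calls of a selected gene panel are collapsed,
per sample, into a combination code "<u>U<n>N<d>D" giving the counts of
each status (gene order does not matter).  For k genes there are
(k+1)(k+2)/2 distinct codes — the number of weak compositions of k into
three parts — e.g. 15 for a 4-gene panel and 45 for 8 genes.  Codes map
to categories: any pattern with at least one Up and no Down is
"<u>-Up", the single pattern with exactly one Up and one Down is
"1-Up-1-Down", and everything else is "Others".
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .peep import DOWN, NORM, STATUSES, UP
from .stratify import AVE, HIGH, LOW, canonical_label

GROUPS = (HIGH, AVE, LOW)


@dataclass(frozen=True)
class BarcodePattern:
    """Up/Norm/Down counts, the code string, and the category label."""

    n_up: int
    n_norm: int
    n_down: int

    @property
    def size(self) -> int:
        return self.n_up + self.n_norm + self.n_down

    @property
    def code(self) -> str:
        return f"{self.n_up}U{self.n_norm}N{self.n_down}D"

    @property
    def category(self) -> str:
        return categorize(self)


def categorize(pattern: BarcodePattern) -> str:
    """Category of a pattern: pure-Up counts, the 1-Up-1-Down pair, or Others."""
    if pattern.n_up >= 1 and pattern.n_down == 0:
        return f"{pattern.n_up}-Up"
    if pattern.n_up == 1 and pattern.n_down == 1:
        return "1-Up-1-Down"
    return "Others"


def categories_for_panel(n_genes: int) -> list[str]:
    """All category labels possible for an n-gene panel, in reporting order."""
    cats = [f"{k}-Up" for k in range(n_genes, 0, -1)]
    if n_genes >= 2:
        cats.append("1-Up-1-Down")
    cats.append("Others")
    return cats


def make_combination(statuses: Sequence[str]) -> BarcodePattern:
    """Collapse an ordered status list to its (order-invariant) pattern."""
    if len(statuses) == 0:
        raise ValueError("status list must be non-empty")
    bad = [s for s in statuses if s not in STATUSES]
    if bad:
        raise ValueError(f"unknown statuses: {bad}")
    c = Counter(statuses)
    return BarcodePattern(n_up=c[UP], n_norm=c[NORM], n_down=c[DOWN])


def enumerate_patterns(n_genes: int) -> list[BarcodePattern]:
    """All distinct (n_up, n_norm, n_down) compositions of n_genes.

    Stars and bars: there are (n+1)(n+2)/2 of them.  Ordered with Up
    counts descending then Down ascending, which reproduces the
    conventional 15-row listing for a 4-gene panel.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    out = [
        BarcodePattern(u, n_genes - u - d, d)
        for d in range(n_genes + 1)
        for u in range(n_genes - d, -1, -1)
    ]
    assert len(out) == (n_genes + 1) * (n_genes + 2) // 2
    return out


@dataclass(frozen=True)
class DonorBarcode:
    donor_id: str
    panel: tuple[str, ...]
    statuses: tuple[str, ...]
    pattern: BarcodePattern

    def __post_init__(self) -> None:
        if len(self.statuses) != len(self.panel):
            raise ValueError("statuses length must equal panel length")


def barcode_cohort(peep: pd.DataFrame, panel: Sequence[str]) -> list[DonorBarcode]:
    """One DonorBarcode per donor from the status matrix, panel order fixed."""
    missing = [g for g in panel if g not in peep.columns]
    if missing:
        raise ValueError(f"panel genes absent from status matrix: {missing}")
    panel = tuple(panel)
    out = []
    for donor_id, row in peep[list(panel)].iterrows():
        statuses = tuple(row.tolist())
        out.append(
            DonorBarcode(
                donor_id=donor_id,
                panel=panel,
                statuses=statuses,
                pattern=make_combination(statuses),
            )
        )
    return out


def category_frequencies(
    barcodes: Sequence[DonorBarcode], labels: Mapping[str, str]
) -> pd.DataFrame:
    """Count and fraction of each category within each responder group.

    Zero rows are included so every (group, category) cell is present;
    fractions within a group sum to 1 (groups with no donors get NaN
    fractions).
    """
    unlabelled = [b.donor_id for b in barcodes if b.donor_id not in labels]
    if unlabelled:
        raise ValueError(f"unlabelled donors: {unlabelled[:5]}")
    n_genes = len(barcodes[0].panel) if barcodes else 4
    cats = categories_for_panel(n_genes)
    counts: dict[tuple[str, str], int] = {
        (g, c): 0 for g in GROUPS for c in cats
    }
    group_n = Counter()
    for b in barcodes:
        g = canonical_label(labels[b.donor_id])
        counts[(g, b.pattern.category)] += 1
        group_n[g] += 1
    rows = []
    for g in GROUPS:
        for c in cats:
            k = counts[(g, c)]
            frac = k / group_n[g] if group_n[g] else float("nan")
            rows.append({"group": g, "category": c, "count": k, "fraction": frac})
    return pd.DataFrame(rows)
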