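"""Personalized perturbation profiles (PEEP).

Rather than comparing group means, each sample's Log2 expression level
for each gene is compared to a per-gene "normal range" derived from the
control donors (the combined Average + Low responders): the control mean
plus or minus one control SD.  A level strictly above the upper cutoff is
called "Up", strictly below the lower cutoff "Down", otherwise "Norm";
"Perturbed" means Up or Down.  Group summaries report the Up/Down/
Perturbed counts and percentages per responder group, including the
pooled Ave+Low and Total rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .stratify import AVE, HIGH, LOW, canonical_label

UP = "Up"
NORM = "Norm"
DOWN = "Down"
STATUSES = (UP, NORM, DOWN)

#: Group summary rows, in reporting order.
SUMMARY_GROUPS = (HIGH, AVE, LOW, "Ave+Low", "Total")


@dataclass(frozen=True)
class ControlStats:
    """Per-gene control (Ave+Low) mean/SD and the ±1 SD perturbation cutoffs."""

    gene: str
    m_ctrl: float
    sd_ctrl: float
    up_cutoff: float = field(init=False)
    down_cutoff: float = field(init=False)

    def __post_init__(self) -> None:
        if self.sd_ctrl < 0:
            raise ValueError(f"{self.gene}: sd_ctrl must be non-negative")
        object.__setattr__(self, "up_cutoff", self.m_ctrl + self.sd_ctrl)
        object.__setattr__(self, "down_cutoff", self.m_ctrl - self.sd_ctrl)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (half-up), e.g. 34.05 -> 34.1."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def fit_control_stats(
    expr: pd.DataFrame, control_donors: Iterable[str]
) -> list[ControlStats]:
    """Per-gene mean and sample SD over the control donors, with cutoffs."""
    controls = list(control_donors)
    if len(controls) < 2:
        raise ValueError(f"need at least 2 control donors, got {len(controls)}")
    missing = [d for d in controls if d not in expr.index]
    if missing:
        raise ValueError(f"control donors absent from expression matrix: {missing}")
    sub = expr.loc[controls]
    return [
        ControlStats(
            gene=g, m_ctrl=float(sub[g].mean()), sd_ctrl=float(sub[g].std(ddof=1))
        )
        for g in expr.columns
    ]


def call_status(level: float, cs: ControlStats) -> str:
    """Up / Norm / Down for one level; cutoff ties resolve to Norm."""
    if level > cs.up_cutoff:
        return UP
    if level < cs.down_cutoff:
        return DOWN
    return NORM


def build_peep(expr: pd.DataFrame, stats: Sequence[ControlStats]) -> pd.DataFrame:
    """Donor x gene status matrix against per-gene control cutoffs."""
    by_gene = {cs.gene: cs for cs in stats}
    missing = [g for g in expr.columns if g not in by_gene]
    if missing:
        raise ValueError(f"no control stats for genes: {missing}")
    out = {}
    for g in expr.columns:
        cs = by_gene[g]
        col = expr[g].to_numpy(dtype=float)
        statuses = np.full(col.shape, NORM, dtype=object)
        statuses[col > cs.up_cutoff] = UP
        statuses[col < cs.down_cutoff] = DOWN
        out[g] = statuses
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def summarize_groups(
    peep: pd.DataFrame, labels: Mapping[str, str]
) -> pd.DataFrame:
    """Per gene and responder group, Perturbed/Up/Down counts and percentages.

    ``labels`` maps donor_id -> responder label.  Rows are emitted for
    High, Ave, Low, the pooled Ave+Low, and Total; percentages are
    100 * count / group size rounded half-up to one decimal.
    """
    unlabelled = [d for d in peep.index if d not in labels]
    if unlabelled:
        raise ValueError(f"unlabelled donors: {unlabelled[:5]}")
    canon = {d: canonical_label(labels[d]) for d in peep.index}
    members: dict[str, list[str]] = {
        HIGH: [d for d, l in canon.items() if l == HIGH],
        AVE: [d for d, l in canon.items() if l == AVE],
        LOW: [d for d, l in canon.items() if l == LOW],
    }
    members["Ave+Low"] = members[AVE] + members[LOW]
    members["Total"] = list(peep.index)
    rows = []
    for gene in peep.columns:
        for group in SUMMARY_GROUPS:
            donors = members[group]
            n = len(donors)
            col = peep.loc[donors, gene] if n else peep.loc[[], gene]
            n_up = int((col == UP).sum())
            n_down = int((col == DOWN).sum())
            n_pert = n_up + n_down
            pct = lambda k: round_half_up(100.0 * k / n, 1) if n else float("nan")
            rows.append(
                {
                    "gene": gene,
                    "group": group,
                    "n_group": n,
                    "n_perturbed": n_pert,
                    "n_up": n_up,
                    "n_down": n_down,
                    "pct_perturbed": pct(n_pert),
                    "pct_up": pct(n_up),
                    "pct_down": pct(n_down),
                }
            )
    return pd.DataFrame(rows)


def control_stats_frame(stats: Sequence[ControlStats]) -> pd.DataFrame:
    """Tabular view of control stats (gene, mean, sd, cutoffs)."""
    return pd.DataFrame(
        [
            {
                "gene": cs.gene,
                "mean": cs.m_ctrl,
                "sd": cs.sd_ctrl,
                "up_cutoff": cs.up_cutoff,
                "down_cutoff": cs.down_cutoff,
            }
            for cs in stats
        ]
    )
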