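"""Candidate-gene screen on a Log2 expression matrix.

Per gene, the linear fold change of the case-group mean over the pooled
control-group mean is computed as 2**(difference of Log2 means) and
folded to a signed convention (ratio if >= 1, else -1/ratio, so a
two-fold repression reads -2), together with a two-sided Welch t-test
p-value on the Log2 levels.  A gene is selected when p < p_cutoff and
|signed fold change| exceeds fc_cutoff, both strictly; no multiple-
testing correction is applied.  This is a deliberately simple location
screen for pipeline completeness, not a mixed-model microarray analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stratify import canonical_label


@dataclass(frozen=True)
class ScreenResult:
    gene: str
    fold_change: float   # signed linear scale; |fold_change| >= 1
    p_value: float
    selected: bool


def signed_fold_change(log2_case_mean: float, log2_ctrl_mean: float) -> float:
    """Linear ratio folded so down-regulation is the negative reciprocal."""
    ratio = 2.0 ** (log2_case_mean - log2_ctrl_mean)
    return ratio if ratio >= 1.0 else -1.0 / ratio


def screen_genes(
    expr: pd.DataFrame,
    labels: Mapping[str, str],
    case_group: str = "High",
    control_groups: Sequence[str] = ("Ave", "Low"),
    fc_cutoff: float = 1.2,
    p_cutoff: float = 0.05,
) -> list[ScreenResult]:
    """Screen every gene for a case-vs-pooled-control expression shift."""
    case_group = canonical_label(case_group)
    controls = {canonical_label(g) for g in control_groups}
    unlabelled = [d for d in expr.index if d not in labels]
    if unlabelled:
        raise ValueError(f"unlabelled donors: {unlabelled[:5]}")
    canon = {d: canonical_label(labels[d]) for d in expr.index}
    case_donors = [d for d in expr.index if canon[d] == case_group]
    ctrl_donors = [d for d in expr.index if canon[d] in controls]
    if len(case_donors) < 2 or len(ctrl_donors) < 2:
        raise ValueError(
            f"need >= 2 donors per side, got {len(case_donors)} case / "
            f"{len(ctrl_donors)} control"
        )
    results = []
    case = expr.loc[case_donors]
    ctrl = expr.loc[ctrl_donors]
    for gene in expr.columns:
        x = case[gene].to_numpy(dtype=float)
        y = ctrl[gene].to_numpy(dtype=float)
        fc = signed_fold_change(float(x.mean()), float(y.mean()))
        if np.allclose(x.std(), 0) and np.allclose(y.std(), 0) and x.mean() == y.mean():
            p = 1.0  # degenerate: identical constant groups
        else:
            p = float(sps.ttest_ind(x, y, equal_var=False).pvalue)
        selected = (p < p_cutoff) and (fc > fc_cutoff or fc < -fc_cutoff)
        results.append(ScreenResult(gene=gene, fold_change=fc, p_value=p, selected=selected))
    return results


def screen_frame(results: Sequence[ScreenResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "fold_change": r.fold_change,
                "p_value": r.p_value,
                "selected": r.selected,
            }
            for r in results
        ]
    )
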