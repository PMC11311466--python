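"""Responder stratification by the cohort mean ± 1 SD rule.

A cohort of donors is characterized by its anti-IgE-induced histamine
release percentages.  Donors releasing more than one standard deviation
above the cohort mean are High responders, those more than one SD below
are Low responders, and everyone in between (boundaries included) is an
Average ("Ave") responder.

Statistics may be fitted on one cohort and applied to another: patient
samples are classified against a previously established normal-donor
baseline rather than against their own (small) cohort.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: Canonical responder labels.
HIGH = "High"
AVE = "Ave"
LOW = "Low"
LABELS = (HIGH, AVE, LOW)

#: Accepted spellings on input, mapped to canonical labels.
LABEL_ALIASES = {"High": HIGH, "Ave": AVE, "Average": AVE, "Low": LOW}


def canonical_label(label: str) -> str:
    """Map an input label spelling to its canonical form ("Average" -> "Ave")."""
    try:
        return LABEL_ALIASES[label]
    except KeyError:
        raise ValueError(
            f"unknown responder label {label!r}; expected one of {sorted(LABEL_ALIASES)}"
        ) from None


@dataclass(frozen=True)
class DonorRecord:
    """One donor: histamine release percentage and (optionally) a responder label."""

    donor_id: str
    release_pct: float
    label: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.release_pct <= 100.0:
            raise ValueError(
                f"donor {self.donor_id!r}: release_pct {self.release_pct} outside [0, 100]"
            )


@dataclass(frozen=True)
class ReleaseStats:
    """Cohort histamine-release statistics and the derived group cutoffs.

    ``upper_cutoff_pct`` = mean + SD and ``lower_cutoff_pct`` = mean - SD
    delimit the Average-responder range.
    """

    mean_pct: float
    sd_pct: float
    n: int
    upper_cutoff_pct: float = field(init=False)
    lower_cutoff_pct: float = field(init=False)

    def __post_init__(self) -> None:
        if self.sd_pct < 0:
            raise ValueError(f"sd_pct must be non-negative, got {self.sd_pct}")
        object.__setattr__(self, "upper_cutoff_pct", self.mean_pct + self.sd_pct)
        object.__setattr__(self, "lower_cutoff_pct", self.mean_pct - self.sd_pct)


def fit_release_stats(values: Sequence[float]) -> ReleaseStats:
    """Fit mean, sample SD (n-1 denominator) and the ±1 SD cutoffs.

    Requires at least two values; the sample SD is undefined otherwise.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError(f"need at least 2 release values to fit stats, got {arr.size}")
    return ReleaseStats(
        mean_pct=float(arr.mean()), sd_pct=float(arr.std(ddof=1)), n=int(arr.size)
    )


def classify_responder(release_pct: float, stats: ReleaseStats) -> str:
    """Classify one release value against fitted cutoffs.

    Strictly above the upper cutoff -> High; strictly below the lower
    cutoff -> Low; otherwise Ave (values exactly on a cutoff are Ave).
    """
    if release_pct > stats.upper_cutoff_pct:
        return HIGH
    if release_pct < stats.lower_cutoff_pct:
        return LOW
    return AVE


def stratify(
    cohort: Iterable[DonorRecord], stats: ReleaseStats | None = None
) -> tuple[list[DonorRecord], dict[str, int]]:
    """Label every donor and return (labelled cohort, group counts).

    If ``stats`` is omitted the cutoffs are refit to the supplied cohort;
    pass previously fitted stats to classify new samples against a
    reference baseline.
    """
    donors = list(cohort)
    ids = [d.donor_id for d in donors]
    if len(set(ids)) != len(ids):
        dupes = [k for k, c in Counter(ids).items() if c > 1]
        raise ValueError(f"duplicate donor ids: {dupes}")
    if stats is None:
        stats = fit_release_stats([d.release_pct for d in donors])
    labelled = [
        DonorRecord(d.donor_id, d.release_pct, classify_responder(d.release_pct, stats))
        for d in donors
    ]
    counts = {lab: 0 for lab in LABELS}
    for d in labelled:
        counts[d.label] += 1
    return labelled, counts
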