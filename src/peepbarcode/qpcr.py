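"""qPCR quantity normalization to Log2 expression levels.

Each plate carries, for every target gene, triplicate-mean quantities for
the donor samples (Qs) and for a plate-to-plate reference cDNA control
(Qc), plus the matching GAPDH quantities (Gs, Gc).  Plate effects are
removed by normalization factors

    NFq = Qc / mean over plates of Qc   (per target gene)
    NFg = Gc / mean over plates of Gc

and the within-sample expression level referenced to GAPDH is

    level = (Qs / NFq) / (Gs / NFg)

which is finally Log2-converted, so a level above the reference ratio is
positive and below is negative.  Because both factors are ratios to a
cross-plate mean, multiplying every quantity on one plate by arbitrary
positive constants (each channel independently) leaves levels unchanged.

Ct-level input is optional: a standard curve (Ct regressed on log10
quantity) converts Ct values to quantities; quantities are the canonical
internal representation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class StandardCurve:
    """Linear standard curve Ct = slope * log10(quantity) + intercept.

    A valid amplification curve has slope < 0 (about -3.32 per decade at
    100% efficiency).
    """

    gene: str
    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if not self.slope < 0:
            raise ValueError(
                f"standard curve for {self.gene!r}: slope must be negative, got {self.slope}"
            )


def fit_standard_curve(points: Sequence[tuple[float, float]], gene: str = "") -> StandardCurve:
    """Least-squares fit of Ct on log10(quantity) from (quantity, Ct) pairs."""
    if len(points) < 2:
        raise ValueError("need at least 2 standard-curve points")
    q = np.asarray([p[0] for p in points], dtype=float)
    ct = np.asarray([p[1] for p in points], dtype=float)
    if np.any(q <= 0):
        raise ValueError("standard-curve quantities must be positive")
    logq = np.log10(q)
    if np.unique(logq).size < 2:
        raise ValueError("standard-curve points must span at least 2 distinct quantities")
    slope, intercept = np.polynomial.polynomial.polyfit(logq, ct, 1)[::-1]
    return StandardCurve(gene=gene, slope=float(slope), intercept=float(intercept))


def ct_to_quantity(ct: float, curve: StandardCurve) -> float:
    """Invert the standard curve: quantity = 10**((ct - intercept) / slope)."""
    return float(10.0 ** ((ct - curve.intercept) / curve.slope))


@dataclass(frozen=True)
class PlateMeasurement:
    """One donor x gene qPCR observation with its plate's reference control."""

    plate_id: str
    donor_id: str
    gene: str
    Qs: float
    Gs: float
    Qc: float
    Gc: float

    def __post_init__(self) -> None:
        for name in ("Qs", "Gs", "Qc", "Gc"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(
                    f"plate {self.plate_id!r} donor {self.donor_id!r} gene {self.gene!r}: "
                    f"{name} must be positive and finite, got {v}"
                )


@dataclass(frozen=True)
class NormalizationFactors:
    plate_id: str
    gene: str
    NFq: float
    NFg: float

    def __post_init__(self) -> None:
        if not (self.NFq > 0 and self.NFg > 0):
            raise ValueError("normalization factors must be positive")


def normalization_factors(
    plate_controls: Iterable[tuple[str, str, float, float]],
) -> list[NormalizationFactors]:
    """Per-plate factors NFq = Qc / mean(Qc), NFg = Gc / mean(Gc).

    ``plate_controls`` holds one (plate_id, gene, Qc, Gc) tuple per
    plate x gene; the mean is the unweighted mean over the plates that
    ran that gene, so per gene the returned NFq (and NFg) average to 1.
    """
    df = pd.DataFrame(plate_controls, columns=["plate_id", "gene", "Qc", "Gc"])
    if df.duplicated(["plate_id", "gene"]).any():
        dupes = df[df.duplicated(["plate_id", "gene"], keep=False)]
        raise ValueError(
            "duplicate plate control for "
            + ", ".join(f"({r.plate_id}, {r.gene})" for r in dupes.itertuples())
        )
    if (df[["Qc", "Gc"]] <= 0).any().any():
        raise ValueError("plate control quantities must be positive")
    out = []
    for gene, grp in df.groupby("gene", sort=False):
        qbar = grp["Qc"].mean()
        gbar = grp["Gc"].mean()
        for r in grp.itertuples():
            out.append(
                NormalizationFactors(
                    plate_id=r.plate_id, gene=gene, NFq=r.Qc / qbar, NFg=r.Gc / gbar
                )
            )
    return out


def expression_level(m: PlateMeasurement, nf: NormalizationFactors) -> float:
    """GAPDH-referenced, plate-normalized level (Qs/NFq) / (Gs/NFg)."""
    if (m.plate_id, m.gene) != (nf.plate_id, nf.gene):
        raise ValueError(
            f"measurement ({m.plate_id}, {m.gene}) does not match "
            f"factors ({nf.plate_id}, {nf.gene})"
        )
    return (m.Qs / nf.NFq) / (m.Gs / nf.NFg)


def assemble_log2_matrix(levels: Iterable[tuple[str, str, float]]) -> pd.DataFrame:
    """Pivot (donor, gene, linear level) triples into a Log2 donor x gene matrix.

    Levels must be strictly positive (Log2 of a zero/negative quantity is
    undefined; no limit-of-detection imputation is attempted) and unique
    per donor x gene.
    """
    df = pd.DataFrame(levels, columns=["donor_id", "gene", "level"])
    bad = df[~(df["level"] > 0) | ~np.isfinite(df["level"])]
    if len(bad):
        r = bad.iloc[0]
        raise ValueError(
            f"non-positive expression level for donor {r.donor_id!r} gene {r.gene!r}: {r.level}"
        )
    if df.duplicated(["donor_id", "gene"]).any():
        r = df[df.duplicated(["donor_id", "gene"])].iloc[0]
        raise ValueError(f"duplicate level for donor {r.donor_id!r} gene {r.gene!r}")
    mat = df.pivot(index="donor_id", columns="gene", values="level")
    if mat.isna().any().any():
        missing = [
            (d, g) for d in mat.index for g in mat.columns if pd.isna(mat.at[d, g])
        ]
        raise ValueError(f"missing donor x gene levels: {missing[:5]}")
    # preserve first-appearance order of donors and genes
    mat = mat.loc[
        df["donor_id"].drop_duplicates().tolist(), df["gene"].drop_duplicates().tolist()
    ]
    return np.log2(mat)


def normalize_plates(plates: pd.DataFrame) -> pd.DataFrame:
    """Full normalization: a plates table to a donor x gene Log2 matrix.

    ``plates`` needs columns plate_id, donor_id, gene, Qs, Gs, Qc, Gc with
    one row per donor x gene; Qc/Gc must agree within a plate x gene.
    """
    required = ["plate_id", "donor_id", "gene", "Qs", "Gs", "Qc", "Gc"]
    missing = [c for c in required if c not in plates.columns]
    if missing:
        raise ValueError(f"plates table missing columns: {missing}")
    ctrl = plates[["plate_id", "gene", "Qc", "Gc"]].drop_duplicates()
    if ctrl.duplicated(["plate_id", "gene"]).any():
        r = ctrl[ctrl.duplicated(["plate_id", "gene"])].iloc[0]
        raise ValueError(
            f"inconsistent plate controls within plate {r.plate_id!r} gene {r.gene!r}"
        )
    nfs = {
        (nf.plate_id, nf.gene): nf
        for nf in normalization_factors(list(ctrl.itertuples(index=False, name=None)))
    }
    triples = []
    for r in plates.itertuples():
        m = PlateMeasurement(
            plate_id=r.plate_id, donor_id=r.donor_id, gene=r.gene,
            Qs=r.Qs, Gs=r.Gs, Qc=r.Qc, Gc=r.Gc,
        )
        triples.append((r.donor_id, r.gene, expression_level(m, nfs[(r.plate_id, r.gene)])))
    return assemble_log2_matrix(triples)
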