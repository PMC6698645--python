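"""Triplex real-time PCR quantification of mtDNA deletion level.

The assay amplifies MT-ND1, MT-ND4 and the D-loop from single-fibre
lysates against a plasmid standard curve. Deletion metrics:

    del(ND4/ND1)  = (1 - ND4/ND1) * 100
    del(ND1/Dloop) = (1 - ND1/Dloop) * 100
    del(ND4/Dloop) = (1 - ND4/Dloop) * 100

Because the D-loop can carry a third (7S) DNA strand, coding targets can
appear up to 33% "deleted" relative to the D-loop in deletion-free fibres;
only values strictly above 33% indicate a genuine deletion species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

TARGETS = ("ND1", "ND4", "DLOOP")

#: D-loop triple-strand rule: percent-deletion values above this indicate
#: a true deletion of the coding target.
DLOOP_THRESHOLD_PCT = 33.0

DELETION_CLASSES = ("none", "ND4_deleted", "ND1_deleted", "both")


class TriplexError(ValueError):
    pass


@dataclass(frozen=True)
class StandardCurve:
    """Log-linear Cq vs log10(copies) calibration."""

    slope: float       # Cq per log10 copies; negative
    intercept: float   # Cq at 1 copy
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise TriplexError(f"standard-curve slope must be negative, got {self.slope}")

    @property
    def efficiency(self) -> float:
        """Amplification efficiency; 1.0 means perfect doubling per cycle."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


@dataclass(frozen=True)
class TriplexResult:
    fibre_id: str
    copies_nd1: float
    copies_nd4: float
    copies_dloop: float
    del_nd4_nd1_pct: float
    nd1_dloop_pct: float
    nd4_dloop_pct: float
    deletion_class: str
    qc_flags: tuple[str, ...] = ()


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """Fit Cq = intercept + slope*log10(copies) to a dilution series.

    ``points`` are (known copies, Cq) pairs; at least two distinct
    dilution levels are required.
    """
    if any(c <= 0 for c, _ in points):
        raise TriplexError("standard copies must be positive")
    x = np.log10([c for c, _ in points])
    y = np.array([q for _, q in points], dtype=float)
    if len(set(np.round(x, 12))) < 2:
        raise TriplexError("need >= 2 distinct dilution levels")
    X = np.column_stack([np.ones(len(x)), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return StandardCurve(slope=float(coef[1]), intercept=float(coef[0]), r_squared=r2)


def cq_to_copies(cq: float, curve: StandardCurve) -> float:
    """Invert the standard curve: copies = 10**((cq - intercept)/slope)."""
    return 10.0 ** ((cq - curve.intercept) / curve.slope)


def aggregate_replicates(cqs: Sequence[float]) -> tuple[float, bool]:
    """Median Cq of 1-3 replicates; QC flag when the range exceeds 0.5 cycles."""
    if len(cqs) == 0:
        raise TriplexError("no replicate Cq values")
    if any(not math.isfinite(q) for q in cqs):
        raise TriplexError("non-finite Cq value")
    med = float(np.median(cqs))
    flag = (max(cqs) - min(cqs)) > 0.5
    return med, flag


def deletion_metrics(
    copies_nd1: float, copies_nd4: float, copies_dloop: float
) -> tuple[float, float, float]:
    """The three percent-deletion metrics (ND4/ND1, ND1/Dloop, ND4/Dloop).

    Values are not clipped at zero: small negatives are legitimate noise
    and are reported as measured.
    """
    for name, v in (("ND1", copies_nd1), ("ND4", copies_nd4), ("DLOOP", copies_dloop)):
        if v <= 0:
            raise TriplexError(f"{name} copies must be positive, got {v}")
    return (
        (1.0 - copies_nd4 / copies_nd1) * 100.0,
        (1.0 - copies_nd1 / copies_dloop) * 100.0,
        (1.0 - copies_nd4 / copies_dloop) * 100.0,
    )


def classify_triplex(
    nd1_dloop_pct: float,
    nd4_dloop_pct: float,
    threshold: float = DLOOP_THRESHOLD_PCT,
) -> str:
    """Deletion class from the D-loop-relative metrics (strict > threshold)."""
    nd1_del = nd1_dloop_pct > threshold
    nd4_del = nd4_dloop_pct > threshold
    if nd1_del and nd4_del:
        return "both"
    if nd4_del:
        return "ND4_deleted"
    if nd1_del:
        return "ND1_deleted"
    return "none"


def quantify_plate(
    plate: pd.DataFrame,
    standards: pd.DataFrame,
    threshold: float = DLOOP_THRESHOLD_PCT,
) -> pd.DataFrame:
    """Quantify every fibre on a plate.

    ``plate`` columns: sample_id, target in {ND1, ND4, DLOOP}, cq,
    replicate. ``standards`` columns: target, copies, cq. One standard
    curve is fitted per target and each fibre's replicate-median Cq is
    converted to absolute copies.
    """
    curves: dict[str, StandardCurve] = {}
    for t in TARGETS:
        pts = standards[standards["target"] == t]
        if pts.empty:
            raise TriplexError(f"no standard series for target {t}")
        curves[t] = fit_standard_curve(list(zip(pts["copies"], pts["cq"])))

    rows = []
    for sample_id, g in plate.groupby("sample_id", sort=True):
        copies: dict[str, float] = {}
        flags: list[str] = []
        for t in TARGETS:
            cqs = g.loc[g["target"] == t, "cq"].tolist()
            if not cqs:
                raise TriplexError(f"sample {sample_id}: missing target {t}")
            med, flagged = aggregate_replicates(cqs)
            if flagged:
                flags.append(f"{t}_replicate_range")
            copies[t] = cq_to_copies(med, curves[t])
        m_nd4nd1, m_nd1dl, m_nd4dl = deletion_metrics(
            copies["ND1"], copies["ND4"], copies["DLOOP"]
        )
        res = TriplexResult(
            fibre_id=str(sample_id),
            copies_nd1=copies["ND1"],
            copies_nd4=copies["ND4"],
            copies_dloop=copies["DLOOP"],
            del_nd4_nd1_pct=m_nd4nd1,
            nd1_dloop_pct=m_nd1dl,
            nd4_dloop_pct=m_nd4dl,
            deletion_class=classify_triplex(m_nd1dl, m_nd4dl, threshold),
            qc_flags=tuple(flags),
        )
        rows.append(res.__dict__ | {"qc_flags": ";".join(flags)})
    return pd.DataFrame(rows)


def copy_number_summary(
    results: pd.DataFrame, classified: pd.DataFrame
) -> pd.DataFrame:
    """Median/quartile copy-number summaries per respiratory-chain class.

    Joins triplex results to classified fibres on fibre_id and summarises
    D-loop (total) and ND4 (wild-type proxy) copies per MRC class. Any
    group comparison test on top of this is a routine library call
    (e.g. scipy.stats.mannwhitneyu) and is left to the caller.
    """
    merged = results.merge(
        classified[["fibre_id", "mrc_class"]], on="fibre_id", how="inner"
    )
    if merged.empty:
        raise TriplexError("no overlap between triplex results and classified fibres")
    recs = []
    for mrc, g in merged.groupby("mrc_class", sort=True):
        for col in ("copies_dloop", "copies_nd4"):
            q1, med, q3 = np.percentile(g[col], [25, 50, 75])
            recs.append(
                {
                    "mrc_class": mrc,
                    "quantity": col,
                    "n": len(g),
                    "q1": q1,
                    "median": med,
                    "q3": q3,
                }
            )
    return pd.DataFrame(recs)
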