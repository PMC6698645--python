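"""Single-molecule PCR (smPCR) limiting-dilution analysis.

At limiting dilution the number of template molecules per well is
Poisson-distributed; the fraction of positive wells p relates to the mean
occupancy by lambda = -ln(1 - p) (the Poisson zero class). Keeping
p <= 1/4 across a 96-well plate makes nearly every positive well derive
from a single molecule, so positive-well counts per deletion species give
artefact-free species proportions within a cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

#: Operating point of the dilution protocol: at most 1 in 4 wells positive.
TARGET_POSITIVE_FRACTION = 0.25


class SmpcrError(ValueError):
    pass


@dataclass(frozen=True)
class OccupancyEstimate:
    p_positive: float
    lam: float
    ci_lambda: tuple[float, float]


@dataclass(frozen=True)
class SpeciesCount:
    size_kb: float          # deletion size in kb, as reported
    count: int              # positive wells carrying this species
    proportion: float
    ci: tuple[float, float]


@dataclass(frozen=True)
class CellSmpcrSummary:
    cell_id: str
    patient_id: str
    species: tuple[SpeciesCount, ...]   # sorted by size_kb
    n_species: int
    largest_most_prevalent: bool | None  # None: single species or tie
    flags: tuple[str, ...] = ()


def estimate_lambda(
    n_positive: int, n_wells: int, alpha: float = 0.05
) -> OccupancyEstimate:
    """Poisson mean occupancy from the positive-well fraction.

    lambda = -ln(1 - p); the CI transforms a Wilson interval on p. All 96
    wells positive leaves lambda unbounded and is rejected with advice to
    dilute further.
    """
    if not 0 <= n_positive <= n_wells or n_wells < 1:
        raise SmpcrError(f"bad well counts {n_positive}/{n_wells}")
    if n_positive == n_wells:
        raise SmpcrError(
            "every well positive: occupancy unbounded; dilute the template further"
        )
    p = n_positive / n_wells
    lo, hi = proportion_confint(n_positive, n_wells, alpha=alpha, method="wilson")
    return OccupancyEstimate(
        p_positive=p,
        lam=-math.log1p(-p),
        ci_lambda=(-math.log1p(-lo), -math.log1p(-min(hi, 1 - 1e-12))),
    )


def dilution_factor(
    current_lambda: float, target_p: float = TARGET_POSITIVE_FRACTION
) -> float:
    """Multiplicative template dilution to reach a target positive fraction."""
    if current_lambda <= 0:
        raise SmpcrError("current occupancy must be positive to plan a dilution")
    if not 0 < target_p < 1:
        raise SmpcrError(f"target positive fraction {target_p} outside (0, 1)")
    return -math.log1p(-target_p) / current_lambda


def multiplicity_probability(lam: float) -> float:
    """P(well holds >= 2 molecules | well positive) at occupancy lambda.

    Quality check on the single-molecule claim; tends to 0 as lambda -> 0.
    """
    if lam < 0:
        raise SmpcrError(f"negative occupancy {lam}")
    if lam == 0:
        return 0.0
    denom = -math.expm1(-lam)            # P(>=1)
    num = denom - lam * math.exp(-lam)   # P(>=2)
    return num / denom


def species_proportions(
    cell_id: str,
    counts: dict[float, int],
    patient_id: str = "",
    alpha: float = 0.05,
) -> CellSmpcrSummary:
    """Per-species proportions of positive wells for one cell.

    ``counts`` maps species size (kb, deletion size as reported) to its
    positive-well count. Proportions are raw fractions of positive wells
    (no Poisson co-occupancy correction; see
    :func:`poisson_corrected_proportions` for the optional corrected
    estimator). Wilson intervals per species.
    """
    counts = {s: c for s, c in counts.items() if c > 0}
    total = sum(counts.values())
    if total == 0:
        raise SmpcrError(f"{cell_id}: no positive wells")
    species = tuple(
        SpeciesCount(
            size_kb=s,
            count=c,
            proportion=c / total,
            ci=tuple(proportion_confint(c, total, alpha=alpha, method="wilson")),
        )
        for s, c in sorted(counts.items())
    )
    return CellSmpcrSummary(
        cell_id=cell_id,
        patient_id=patient_id,
        species=species,
        n_species=len(species),
        largest_most_prevalent=_largest_most_prevalent(
            [s.size_kb for s in species], [s.proportion for s in species]
        ),
    )


def poisson_corrected_proportions(
    counts: dict[float, int], n_wells: int
) -> dict[float, float]:
    """Species proportions corrected for well co-occupancy.

    Observation model: molecules per well ~ Poisson(lambda), identities
    multinomial(q), and a co-occupied well is labelled by its smallest
    genome (largest deletion, PCR size bias). Under that model a positive
    well carries label i (species ordered by descending deletion size,
    tail sums T_i = q_1 + ... + q_i) with probability

        P(label = i | positive) = (exp(-lam*T_{i-1}) - exp(-lam*T_i)) / (1 - exp(-lam)),

    which inverts in closed form: matching observed label fractions gives
    exp(-lam*T_i) = 1 - (1 - exp(-lam)) * F_i with F_i the cumulative
    observed fraction. Sensitivity-analysis companion to the raw
    estimator; at the protocol's operating point the correction is small.
    """
    sizes = sorted(counts)          # ascending deletion size
    k = np.array([counts[s] for s in sizes], dtype=float)
    n_pos = k.sum()
    if n_pos == 0:
        raise SmpcrError("no positive wells")
    if n_pos >= n_wells:
        return {s: counts[s] / n_pos for s in sizes}
    lam = -math.log1p(-n_pos / n_wells)
    order = np.argsort(-np.array(sizes))        # descending deletion size
    cum = np.cumsum(k[order] / n_pos)           # observed cumulative fractions
    surv = 1.0 - (-math.expm1(-lam)) * cum      # exp(-lam * T_i)
    surv = np.clip(surv, 1e-300, 1.0)
    t = -np.log(surv) / lam
    q_desc = np.clip(np.diff(np.concatenate([[0.0], t])), 0.0, None)
    q_desc /= q_desc.sum()
    q = np.empty_like(q_desc)
    q[order] = q_desc
    return {s: float(q[i]) for i, s in enumerate(sizes)}


def _largest_most_prevalent(
    sizes: Sequence[float], proportions: Sequence[float]
) -> bool | None:
    """Is the largest deletion (smallest molecule) strictly most prevalent?

    None for single-species cells; ties in top proportion or in the
    largest size count as not-strictly-prevalent and return False, with
    the tie surfaced by the caller's flags.
    """
    if len(sizes) < 2:
        return None
    top = max(proportions)
    largest = max(sizes)
    winners = [s for s, p in zip(sizes, proportions) if p == top]
    if len(winners) > 1:
        return False
    return winners[0] == largest


def summaries_from_table(table: pd.DataFrame) -> list[CellSmpcrSummary]:
    """Build per-cell summaries from a wide fibre table.

    Expected columns: patient_id, fibre, then size{i}_kb / prop{i} pairs.
    Printed proportions are taken at face value; rows whose proportions do
    not sum to 1 (+-0.02) are flagged, not renormalised, as are size ties.
    """
    out = []
    for r in table.itertuples(index=False):
        d = r._asdict()
        sizes, props = [], []
        for i in (1, 2, 3):
            s, p = d.get(f"size{i}_kb"), d.get(f"prop{i}")
            if pd.notna(s) and pd.notna(p):
                sizes.append(float(s))
                props.append(float(p))
        if not sizes:
            raise SmpcrError(f"fibre {d.get('fibre')}: no species recorded")
        flags = []
        if len(sizes) > 1 and abs(sum(props) - 1.0) > 0.02:
            flags.append(f"proportions_sum_{sum(props):.4f}")
        if len(set(sizes)) < len(sizes):
            flags.append("size_tie")
        species = tuple(
            SpeciesCount(size_kb=s, count=0, proportion=p, ci=(math.nan, math.nan))
            for s, p in sorted(zip(sizes, props))
        )
        out.append(
            CellSmpcrSummary(
                cell_id=str(d["fibre"]),
                patient_id=str(d["patient_id"]),
                species=species,
                n_species=len(species),
                largest_most_prevalent=_largest_most_prevalent(sizes, props),
                flags=tuple(flags),
            )
        )
    return out


def largest_prevalence(
    cells: Sequence[CellSmpcrSummary],
) -> pd.DataFrame:
    """Per-patient fraction of multi-species cells whose largest deletion is
    strictly most prevalent.

    The denominator is cells with >= 2 species; ties (in top proportion or
    largest size) are excluded from the numerator and reported separately.
    Patients without multi-species cells are reported with NaN.
    """
    recs: dict[str, dict[str, int]] = {}
    for c in cells:
        r = recs.setdefault(
            c.patient_id, {"multi": 0, "largest_most_prevalent": 0, "ties": 0}
        )
        if c.n_species >= 2:
            r["multi"] += 1
            if c.largest_most_prevalent:
                r["largest_most_prevalent"] += 1
            top = max(s.proportion for s in c.species)
            n_top = sum(1 for s in c.species if s.proportion == top)
            if n_top > 1 or "size_tie" in c.flags:
                r["ties"] += 1
    rows = []
    for pid, r in sorted(recs.items()):
        frac = r["largest_most_prevalent"] / r["multi"] if r["multi"] else math.nan
        rows.append(
            {
                "patient_id": pid,
                "n_multi_species_cells": r["multi"],
                "n_largest_most_prevalent": r["largest_most_prevalent"],
                "n_ties": r["ties"],
                "fraction": frac,
                "percent": round(100 * frac, 1) if r["multi"] else math.nan,
            }
        )
    return pd.DataFrame(rows)


def multiplicity_distribution(cells: Sequence[CellSmpcrSummary]) -> pd.DataFrame:
    """Counts and percentages of cells with 1, 2, 3, ... deletion species."""
    if not cells:
        raise SmpcrError("no cells")
    counts: dict[int, int] = {}
    for c in cells:
        counts[c.n_species] = counts.get(c.n_species, 0) + 1
    total = len(cells)
    nmax = max(3, max(counts))
    return pd.DataFrame(
        [
            {
                "n_species": k,
                "n_cells": counts.get(k, 0),
                "percent": round(100 * counts.get(k, 0) / total, 1),
            }
            for k in range(1, nmax + 1)
        ]
    )


def read_plate_counts(path) -> pd.DataFrame:
    """Read long-form per-cell species counts.

    Columns: cell_id, patient_id, species_size_kb, positive_well_count,
    n_wells.
    """
    df = pd.read_csv(path, dtype={"cell_id": str, "patient_id": str})
    need = {"cell_id", "patient_id", "species_size_kb", "positive_well_count", "n_wells"}
    missing = need - set(df.columns)
    if missing:
        raise SmpcrError(f"plate table lacks columns: {sorted(missing)}")
    return df


def summaries_from_counts(df: pd.DataFrame) -> list[CellSmpcrSummary]:
    """Per-cell summaries from long-form positive-well counts."""
    out = []
    for (cell_id, patient_id), g in df.groupby(
        ["cell_id", "patient_id"], sort=True
    ):
        counts = {
            float(r.species_size_kb): int(r.positive_well_count)
            for r in g.itertuples(index=False)
        }
        out.append(species_proportions(str(cell_id), counts, str(patient_id)))
    return out
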