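"""Quadruple-immunofluorescence densitometry analysis.

Per-fibre optical densities (OD) for porin (mitochondrial mass), NDUFB8
(complex I) and COX-I (complex IV) are background-corrected, referenced to
a control-fibre regression of each respiratory-chain channel on porin, and
expressed as z-scores. Fibres are then classified into respiratory-chain
groups (CI+CIV+, CI-CIV+, CI+CIV-, CI-CIV-), per-channel expression levels,
mitochondrial-mass bands, and ragged-red-fibre (RRF) status (porin z > 2.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MRC_CLASSES = ("CI+CIV+", "CI-CIV+", "CI+CIV-", "CI-CIV-")
LEVELS = ("normal", "intermediate_plus", "intermediate_minus", "deficient")
MASS_CLASSES = ("very_low", "low", "normal", "high", "very_high")
FIBRE_TYPES = ("I", "IIa", "IIx/IIb", "unknown")


class IfQuantError(ValueError):
    pass


@dataclass(frozen=True)
class FibreOD:
    """Background-corrected optical densities for one fibre."""

    fibre_id: str
    patient_id: str
    subject_class: str  # "patient" | "control"
    od_porin: float
    od_ndufb8: float
    od_coxi: float
    fibre_type: str = "unknown"

    def __post_init__(self) -> None:
        for name in ("od_porin", "od_ndufb8", "od_coxi"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise IfQuantError(f"{self.fibre_id}: {name}={v} must be finite and >= 0")
        if self.subject_class not in ("patient", "control"):
            raise IfQuantError(f"{self.fibre_id}: bad subject_class {self.subject_class!r}")


@dataclass(frozen=True)
class ControlModel:
    """Control-fibre regression of each channel on porin (linear or log OD)."""

    slope_ndufb8: float
    intercept_ndufb8: float
    resid_sd_ndufb8: float
    slope_coxi: float
    intercept_coxi: float
    resid_sd_coxi: float
    porin_mean: float
    porin_sd: float
    n_controls: int
    log_space: bool = False


@dataclass(frozen=True)
class FibreZ:
    z_porin: float
    z_ndufb8: float
    z_coxi: float


@dataclass(frozen=True)
class ClassifyConfig:
    """Thresholds for fibre classification, all on the z scale.

    ``level_bounds`` split each channel into normal / intermediate(+) /
    intermediate(-) / deficient; ``deficient_cut`` is the single cut that
    decides a channel's "-" in the respiratory-chain class; ``mass_bounds``
    are the four porin-z cuts of the five mass bands; ``rrf_cut`` is the
    strict porin-z threshold for ragged-red fibres.
    """

    level_bounds: tuple[float, float, float] = (-3.0, -4.5, -6.0)
    deficient_cut: float = -3.0
    mass_bounds: tuple[float, float, float, float] = (-3.0, -2.0, 2.0, 3.0)
    rrf_cut: float = 2.5


@dataclass(frozen=True)
class FibreClassification:
    mrc_class: str
    level_ndufb8: str
    level_coxi: str
    mass_class: str
    is_rrf: bool


def background_correct(raw_od: float, npc_mean: float) -> float:
    """Subtract the no-primary-control channel mean, clipped at zero."""
    if raw_od < 0:
        raise IfQuantError(f"raw OD {raw_od} is negative")
    if npc_mean < 0:
        raise IfQuantError(f"background mean {npc_mean} is negative")
    return max(raw_od - npc_mean, 0.0)


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares y = a + b*x; returns (slope, intercept, resid_sd)."""
    n = len(x)
    X = np.column_stack([np.ones(n), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = max(n - 2, 1)
    return float(coef[1]), float(coef[0]), float(np.sqrt(resid @ resid / dof))


def fit_control_model(
    controls: Sequence[FibreOD], log_space: bool = False
) -> ControlModel:
    """Fit the control regression of NDUFB8 and COX-I on porin.

    With ``log_space`` the fit (and later z-scores) use log10 OD; zero ODs
    are rejected in that mode.
    """
    if len(controls) < 3:
        raise IfQuantError(f"need >= 3 control fibres, got {len(controls)}")
    porin = np.array([c.od_porin for c in controls], dtype=float)
    nduf = np.array([c.od_ndufb8 for c in controls], dtype=float)
    coxi = np.array([c.od_coxi for c in controls], dtype=float)
    if log_space:
        if np.any(porin <= 0) or np.any(nduf <= 0) or np.any(coxi <= 0):
            raise IfQuantError("log-space fit requires strictly positive ODs")
        porin, nduf, coxi = np.log10(porin), np.log10(nduf), np.log10(coxi)
    if np.ptp(porin) == 0:
        raise IfQuantError("control porin ODs have zero variance")
    s_n, i_n, r_n = _ols(porin, nduf)
    s_c, i_c, r_c = _ols(porin, coxi)
    return ControlModel(
        slope_ndufb8=s_n, intercept_ndufb8=i_n, resid_sd_ndufb8=r_n,
        slope_coxi=s_c, intercept_coxi=i_c, resid_sd_coxi=r_c,
        porin_mean=float(porin.mean()), porin_sd=float(porin.std(ddof=1)),
        n_controls=len(controls), log_space=log_space,
    )


def zscores(f: FibreOD, m: ControlModel) -> FibreZ:
    """z-scores of a fibre against the control model.

    For the respiratory-chain channels the z-score is the residual from
    the control regression divided by the control residual SD; for porin
    it is the plain standardisation against control porin.
    """
    porin, nduf, coxi = f.od_porin, f.od_ndufb8, f.od_coxi
    if m.log_space:
        if porin <= 0 or nduf <= 0 or coxi <= 0:
            raise IfQuantError(f"{f.fibre_id}: log-space z-scores need positive ODs")
        porin, nduf, coxi = math.log10(porin), math.log10(nduf), math.log10(coxi)

    def _z(obs: float, slope: float, intercept: float, sd: float) -> float:
        resid = obs - (intercept + slope * porin)
        if sd == 0:
            if resid == 0:
                return 0.0
            raise IfQuantError(
                f"{f.fibre_id}: nonzero residual with zero control residual SD"
            )
        return resid / sd

    return FibreZ(
        z_porin=(porin - m.porin_mean) / m.porin_sd,
        z_ndufb8=_z(nduf, m.slope_ndufb8, m.intercept_ndufb8, m.resid_sd_ndufb8),
        z_coxi=_z(coxi, m.slope_coxi, m.intercept_coxi, m.resid_sd_coxi),
    )


def _level(z: float, bounds: tuple[float, float, float]) -> str:
    b1, b2, b3 = bounds
    if z >= b1:
        return "normal"
    if z >= b2:
        return "intermediate_plus"
    if z >= b3:
        return "intermediate_minus"
    return "deficient"


def _mass(z: float, bounds: tuple[float, float, float, float]) -> str:
    b1, b2, b3, b4 = bounds
    if z < b1:
        return "very_low"
    if z < b2:
        return "low"
    if z <= b3:
        return "normal"
    if z <= b4:
        return "high"
    return "very_high"


def classify_fibre(
    z: FibreZ, config: ClassifyConfig | None = None
) -> FibreClassification:
    """Classify one fibre from its z-scores."""
    cfg = config or ClassifyConfig()
    ci_def = z.z_ndufb8 < cfg.deficient_cut
    civ_def = z.z_coxi < cfg.deficient_cut
    mrc = f"CI{'-' if ci_def else '+'}CIV{'-' if civ_def else '+'}"
    return FibreClassification(
        mrc_class=mrc,
        level_ndufb8=_level(z.z_ndufb8, cfg.level_bounds),
        level_coxi=_level(z.z_coxi, cfg.level_bounds),
        mass_class=_mass(z.z_porin, cfg.mass_bounds),
        is_rrf=z.z_porin > cfg.rrf_cut,
    )


def classify_cohort(
    fibres: Sequence[FibreOD],
    controls: Sequence[FibreOD],
    config: ClassifyConfig | None = None,
    log_space: bool = False,
) -> pd.DataFrame:
    """Fit controls, score and classify every fibre; tidy frame out."""
    model = fit_control_model(controls, log_space=log_space)
    rows = []
    for f in fibres:
        z = zscores(f, model)
        c = classify_fibre(z, config)
        rows.append(
            {
                "fibre_id": f.fibre_id,
                "patient_id": f.patient_id,
                "fibre_type": f.fibre_type,
                "od_porin": f.od_porin,
                "od_ndufb8": f.od_ndufb8,
                "od_coxi": f.od_coxi,
                "z_porin": z.z_porin,
                "z_ndufb8": z.z_ndufb8,
                "z_coxi": z.z_coxi,
                "mrc_class": c.mrc_class,
                "level_ndufb8": c.level_ndufb8,
                "level_coxi": c.level_coxi,
                "mass_class": c.mass_class,
                "is_rrf": c.is_rrf,
            }
        )
    return pd.DataFrame(rows)


def _pct(count: int, total: int) -> float:
    return round(100.0 * count / total, 1)


def contingency_percentages(counts: dict[str, int]) -> pd.DataFrame:
    """Counts -> a one-row-per-category table with percentages to 1 dp."""
    total = sum(counts.values())
    if total == 0:
        raise IfQuantError("empty contingency")
    return pd.DataFrame(
        [
            {"category": k, "count": v, "percent": _pct(v, total)}
            for k, v in counts.items()
        ]
    )


def summarize_cohort(classified: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Cohort contingency summaries.

    Returns MRC-class counts overall, the MRC-class breakdown of RRF
    fibres, and the fibre-type breakdown of RRF fibres, each with
    percentages to one decimal place (empty categories reported as 0).
    """
    if classified.empty:
        raise IfQuantError("no classified fibres to summarize")

    mrc_counts = {
        k: int((classified["mrc_class"] == k).sum()) for k in MRC_CLASSES
    }
    rrf = classified[classified["is_rrf"]]
    rrf_mrc = {k: int((rrf["mrc_class"] == k).sum()) for k in MRC_CLASSES}
    rrf_type = {
        k: int((rrf["fibre_type"] == k).sum()) for k in FIBRE_TYPES
    }

    out = {"mrc": contingency_percentages(mrc_counts)}
    out["rrf_by_mrc"] = (
        contingency_percentages(rrf_mrc)
        if len(rrf)
        else pd.DataFrame(columns=["category", "count", "percent"])
    )
    typed = {k: v for k, v in rrf_type.items() if not (k == "unknown" and v == 0)}
    out["rrf_by_fibre_type"] = (
        contingency_percentages(typed)
        if len(rrf)
        else pd.DataFrame(columns=["category", "count", "percent"])
    )
    return out


def mrc_plot_data(classified: pd.DataFrame) -> pd.DataFrame:
    """Projection used for mitochondrial-respiratory-chain scatter plots."""
    cols = ["fibre_id", "z_ndufb8", "z_coxi", "mass_class"]
    if classified.empty:
        return pd.DataFrame(columns=cols)
    return classified[cols].copy()


def read_fibre_table(path, subject_class: str = "patient") -> list[FibreOD]:
    """Read a fibre OD CSV; optional npc_* columns are subtracted per channel."""
    df = pd.read_csv(path, dtype={"fibre_id": str, "patient_id": str})
    out = []
    for r in df.itertuples(index=False):
        d = r._asdict()
        ods = {}
        for ch in ("porin", "ndufb8", "coxi"):
            raw = float(d[f"od_{ch}"])
            npc = float(d.get(f"npc_{ch}", 0.0) or 0.0)
            ods[ch] = background_correct(raw, npc)
        out.append(
            FibreOD(
                fibre_id=str(d["fibre_id"]),
                patient_id=str(d["patient_id"]),
                subject_class=str(d.get("subject_class", subject_class)),
                od_porin=ods["porin"],
                od_ndufb8=ods["ndufb8"],
                od_coxi=ods["coxi"],
                fibre_type=str(d.get("fibre_type", "unknown") or "unknown"),
            )
        )
    return out
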