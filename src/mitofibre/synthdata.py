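"""Seeded synthetic-data generators.

Each generator emulates the statistical structure one pipeline stage
assumes — mosaic fibre cohorts with deletion-linked deficiency, qPCR
plates driven by a log-linear standard curve with Gaussian Cq noise,
limiting-dilution smPCR plates with Poisson well occupancy, and deletion
breakpoint sets with optionally planted direct repeats — so the whole
package is testable without any external download. Generators are pure
functions of (config, seed): the same seed reproduces the same tables.

The defaults are structural stand-ins for single-fibre cohorts from mtDNA
maintenance-disorder muscle, not reproductions of any particular
patient's heteroplasmy distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import triplex as _triplex
from .breakpoints import FlankPair, flanks_from_reference
from .ifquant import ClassifyConfig, FibreOD
from .mtgenome import DeletionEvent


@dataclass(frozen=True)
class SynthConfig:
    """Shared knobs for all generators; every field has a documented unit.

    Immunofluorescence: control porin OD ~ Normal(porin_mean, porin_sd),
    channel OD = intercept + slope*porin + Normal(0, resid_sd). Patient
    fibres inherit the control model and receive a deficiency z-shift of
    -deficiency_slope * max(0, h - deficiency_threshold) per channel,
    where h is the fibre's deletion level; COX-I shifts only beyond
    ``coxi_extra_threshold`` (complex IV tolerates more deletion than
    complex I, mirroring the two observed deficiency groups).

    Triplex: total mtDNA copies are log-normal; a fraction ``rrf_fraction``
    of high-h fibres carries a hyperproliferation multiplier. Cq noise is
    Gaussian per replicate.

    smPCR: molecules per well ~ Poisson(lam); identities multinomial over
    ``smpcr_proportions``; positive wells are labelled by the smallest
    co-occupying genome (PCR favours short templates).
    """

    seed: int = 0
    # --- immunofluorescence cohort ---
    n_controls: int = 150
    n_patient_fibres: int = 400
    porin_mean: float = 1.0
    porin_sd: float = 0.15
    slope_ndufb8: float = 0.9
    intercept_ndufb8: float = 0.1
    slope_coxi: float = 0.8
    intercept_coxi: float = 0.15
    resid_sd: float = 0.05
    # deletion-level mixture: unaffected fraction + Beta levels for the rest
    unaffected_fraction: float = 0.35
    level_beta_a: float = 4.0
    level_beta_b: float = 1.5
    # deficiency link (z units per unit deletion level above threshold)
    deficiency_threshold: float = 0.45
    deficiency_slope: float = 18.0
    coxi_extra_threshold: float = 0.15
    # RRF / mass model
    rrf_fraction: float = 0.06
    rrf_porin_z: float = 3.5
    # per-fibre measurement noise on patient z-scores (z units); the control
    # residual scatter itself is always resid_sd
    z_noise_sd: float = 0.5
    porin_z_noise_sd: float = 0.5
    # --- triplex ---
    total_copies_log10_mean: float = 4.0
    total_copies_log10_sd: float = 0.25
    rrf_copy_multiplier: float = 3.0
    triple_strand_fraction: float = 1.0
    cq_noise_sd: float = 0.2
    #: Cq noise on the plasmid standard series; None means cq_noise_sd.
    #: Standard-curve noise is shared by every fibre on the plate, so
    #: recovery checks that assume independent fibre errors set this to 0.
    standard_cq_noise_sd: float | None = None
    curve_slope: float = -3.3219
    curve_intercept: float = 38.0
    standard_copies: tuple[float, ...] = (1e2, 1e3, 1e4, 1e5, 1e6, 1e7)
    n_replicates: int = 3
    # --- smPCR ---
    smpcr_lambda: float = 0.25
    smpcr_wells: int = 96
    smpcr_plates: int = 1
    smpcr_sizes_kb: tuple[float, ...] = (5.0, 7.0)
    smpcr_proportions: tuple[float, ...] = (0.3, 0.7)
    # --- breakpoints ---
    reference_length: int = 16569
    n_deletions: int = 30
    repeat_mediated_fraction: float = 0.4
    planted_repeat_length: int = 8
    flank_window: int = 30


def _rng(config: SynthConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng((config.seed, salt))


@dataclass(frozen=True)
class IfCohort:
    controls: list[FibreOD]
    patients: list[FibreOD]
    truth: pd.DataFrame  # fibre_id, deletion_level, true z's and classes


def gen_if_cohort(config: SynthConfig) -> IfCohort:
    """Synthetic control + patient fibre OD tables with known ground truth."""
    rng = _rng(config, 1)
    cfg = ClassifyConfig()

    def _fibres(n, prefix, patient, z_nduf, z_coxi, z_porin):
        porin = config.porin_mean + config.porin_sd * z_porin
        porin = np.clip(porin, 1e-6, None)
        nduf = (
            config.intercept_ndufb8
            + config.slope_ndufb8 * porin
            + config.resid_sd * z_nduf
        )
        coxi = (
            config.intercept_coxi
            + config.slope_coxi * porin
            + config.resid_sd * z_coxi
        )
        return [
            FibreOD(
                fibre_id=f"{prefix}{i:04d}",
                patient_id=patient,
                subject_class="control" if patient == "C1" else "patient",
                od_porin=float(porin[i]),
                od_ndufb8=float(max(nduf[i], 0.0)),
                od_coxi=float(max(coxi[i], 0.0)),
                fibre_type=("I", "IIa", "IIx/IIb")[i % 3],
            )
            for i in range(n)
        ]

    nc = config.n_controls
    controls = _fibres(
        nc, "C", "C1",
        rng.standard_normal(nc), rng.standard_normal(nc), rng.standard_normal(nc),
    )

    npat = config.n_patient_fibres
    affected = rng.random(npat) >= config.unaffected_fraction
    h = np.where(
        affected, rng.beta(config.level_beta_a, config.level_beta_b, npat), 0.0
    )
    shift = -config.deficiency_slope * np.maximum(
        0.0, h - config.deficiency_threshold
    )
    shift_coxi = -config.deficiency_slope * np.maximum(
        0.0, h - config.deficiency_threshold - config.coxi_extra_threshold
    )
    is_rrf = (rng.random(npat) < config.rrf_fraction) & (
        h > config.deficiency_threshold
    )
    z_porin_true = np.where(is_rrf, config.rrf_porin_z, 0.0)
    z_nduf_true = shift
    z_coxi_true = shift_coxi
    patients = _fibres(
        npat, "F", "P1",
        z_nduf_true + config.z_noise_sd * rng.standard_normal(npat),
        z_coxi_true + config.z_noise_sd * rng.standard_normal(npat),
        z_porin_true + config.porin_z_noise_sd * rng.standard_normal(npat),
    )
    truth = pd.DataFrame(
        {
            "fibre_id": [f.fibre_id for f in patients],
            "deletion_level": h,
            "z_ndufb8_true": z_nduf_true,
            "z_coxi_true": z_coxi_true,
            "z_porin_true": z_porin_true,
            "is_rrf_true": is_rrf,
            "mrc_class_true": [
                f"CI{'-' if zn < cfg.deficient_cut else '+'}"
                f"CIV{'-' if zc < cfg.deficient_cut else '+'}"
                for zn, zc in zip(z_nduf_true, z_coxi_true)
            ],
        }
    )
    return IfCohort(controls=controls, patients=patients, truth=truth)


def true_copies(config: SynthConfig, h_nd4: float, h_nd1: float,
                total: float) -> dict[str, float]:
    """Molecule-count observation model for the triplex assay.

    ``total`` molecules; a fraction h_nd4 lacks MT-ND4 and h_nd1 lacks
    MT-ND1; every molecule has a D-loop, counted 1.5x when carrying the
    third (7S) strand. Enumerating molecules gives the template copies
    each probe sees.
    """
    ts = config.triple_strand_fraction
    return {
        "ND1": total * (1.0 - h_nd1),
        "ND4": total * (1.0 - h_nd4),
        "DLOOP": total * (1.0 + 0.5 * ts),
    }


@dataclass(frozen=True)
class TriplexPlate:
    standards: pd.DataFrame
    plate: pd.DataFrame
    truth: pd.DataFrame


def gen_triplex_plate(
    config: SynthConfig, genotypes: pd.DataFrame | None = None
) -> TriplexPlate:
    """Standards + Cq plate for fibres with known genotypes.

    ``genotypes`` columns: fibre_id, h_nd4, h_nd1 (fractions of molecules
    lacking each target). Defaults to a small mixed panel. Cq values are
    curve(copies) + Normal(0, cq_noise_sd), ``n_replicates`` per target.
    """
    rng = _rng(config, 2)
    if genotypes is None:
        genotypes = pd.DataFrame(
            {
                "fibre_id": ["f01", "f02", "f03", "f04"],
                "h_nd4": [0.0, 0.6, 0.0, 0.8],
                "h_nd1": [0.0, 0.0, 0.5, 0.8],
            }
        )
    m, b = config.curve_slope, config.curve_intercept

    std_sd = (
        config.cq_noise_sd
        if config.standard_cq_noise_sd is None
        else config.standard_cq_noise_sd
    )
    std_rows = []
    for c in config.standard_copies:
        for t in _triplex.TARGETS:
            for rep in range(config.n_replicates):
                cq = b + m * np.log10(c) + rng.normal(0, std_sd)
                std_rows.append(
                    {"target": t, "copies": c, "cq": cq, "replicate": rep + 1}
                )

    plate_rows, truth_rows = [], []
    for r in genotypes.itertuples(index=False):
        total = 10.0 ** rng.normal(
            config.total_copies_log10_mean, config.total_copies_log10_sd
        )
        copies = true_copies(config, float(r.h_nd4), float(r.h_nd1), total)
        for t in _triplex.TARGETS:
            ideal = b + m * np.log10(copies[t])
            for rep in range(config.n_replicates):
                plate_rows.append(
                    {
                        "sample_id": r.fibre_id,
                        "target": t,
                        "cq": ideal + rng.normal(0, config.cq_noise_sd),
                        "replicate": rep + 1,
                    }
                )
        del_nd4_nd1, nd1_dl, nd4_dl = _triplex.deletion_metrics(
            copies["ND1"], copies["ND4"], copies["DLOOP"]
        )
        truth_rows.append(
            {
                "fibre_id": r.fibre_id,
                "h_nd4": r.h_nd4,
                "h_nd1": r.h_nd1,
                "total_copies": total,
                **{t: copies[t] for t in _triplex.TARGETS},
                "del_nd4_nd1_pct_true": del_nd4_nd1,
                "nd1_dloop_pct_true": nd1_dl,
                "nd4_dloop_pct_true": nd4_dl,
            }
        )
    return TriplexPlate(
        standards=pd.DataFrame(std_rows),
        plate=pd.DataFrame(plate_rows),
        truth=pd.DataFrame(truth_rows),
    )


def gen_smpcr_plates(config: SynthConfig, cell_id: str = "cell1") -> pd.DataFrame:
    """Per-well outcome table for limiting-dilution plates.

    Molecules per well ~ Poisson(smpcr_lambda); identities multinomial
    over smpcr_proportions; a positive well is labelled by the SMALLEST
    genome present (largest deletion size), modelling PCR preference for
    short templates. Outcome "negative" for empty wells.
    """
    props = np.asarray(config.smpcr_proportions, dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("smpcr_proportions must sum to 1")
    sizes = np.asarray(config.smpcr_sizes_kb, dtype=float)
    rng = _rng(config, 3)
    rows = []
    for plate in range(config.smpcr_plates):
        k = rng.poisson(config.smpcr_lambda, config.smpcr_wells)
        for well, n_mol in enumerate(k):
            if n_mol == 0:
                rows.append(
                    {
                        "cell_id": cell_id,
                        "plate": plate + 1,
                        "well": well + 1,
                        "outcome": "negative",
                    }
                )
                continue
            ids = rng.choice(len(sizes), size=n_mol, p=props)
            label = sizes[ids].max()  # largest deletion = smallest genome
            rows.append(
                {
                    "cell_id": cell_id,
                    "plate": plate + 1,
                    "well": well + 1,
                    "outcome": f"{label:g}kb",
                }
            )
    return pd.DataFrame(rows)


def wells_to_counts(wells: pd.DataFrame) -> dict[float, int]:
    """Collapse a per-well outcome table to species positive-well counts."""
    pos = wells[wells["outcome"] != "negative"]
    counts: dict[float, int] = {}
    for o in pos["outcome"]:
        size = float(o.removesuffix("kb"))
        counts[size] = counts.get(size, 0) + 1
    return counts


@dataclass(frozen=True)
class DeletionSet:
    reference: str
    deletions: list[DeletionEvent]
    flanks: pd.DataFrame   # product_id, five_prime_flank, three_prime_flank
    truth: pd.DataFrame    # product_id, bp5, bp3, planted_repeat_length


def gen_deletion_set(config: SynthConfig, reference: str | None = None) -> DeletionSet:
    """Random circular reference + deletions, some with planted repeats.

    For a repeat-mediated deletion a random k-mer is written into the
    reference so that it ends the retained 5' flank (at bp5) and begins
    the retained 3' flank (at bp3); the finder should recover exactly k.
    """
    rng = _rng(config, 4)
    k = config.planted_repeat_length
    if k >= config.flank_window:
        raise ValueError("planted repeat must be shorter than the flank window")
    n = config.reference_length
    ref = rng.choice(list("ACGT"), size=n) if reference is None else np.array(
        list(reference)
    )
    bases = np.array(list("ACGT"))

    # Keep flank windows of distinct deletions disjoint so a later plant
    # cannot rewrite an earlier deletion's junction.
    used: list[int] = []
    min_gap = 2 * config.flank_window + 2

    def _draw(lo: int, hi: int) -> int:
        for _ in range(1000):
            pos = int(rng.integers(lo, hi))
            if all(abs(pos - u) >= min_gap for u in used):
                used.append(pos)
                return pos
        raise ValueError("could not place deletions with disjoint flank windows")

    dels, truth_rows = [], []
    for i in range(config.n_deletions):
        bp5 = _draw(2000, n // 2 - 1000)
        bp3 = _draw(n // 2 + 1000, n - 1000)
        planted = 0
        if rng.random() < config.repeat_mediated_fraction:
            # A periodic k-mer (e.g. a homopolymer) could extend the
            # junction affix beyond k; redraw until aperiodic.
            while True:
                kmer = rng.choice(bases, size=k)
                if not np.array_equal(kmer[:-1], kmer[1:]):
                    break
            ref[bp5 - k : bp5] = kmer           # ends at bp5 (1-based inclusive)
            ref[bp3 - 1 : bp3 - 1 + k] = kmer   # begins at bp3
            planted = k
        dels.append(DeletionEvent(f"c{i+1}", f"s{i+1}", bp5, bp3))
        truth_rows.append(
            {
                "product_id": f"s{i+1}",
                "bp5": bp5,
                "bp3": bp3,
                "planted_repeat_length": planted,
            }
        )
    ref_str = "".join(ref)
    flank_rows = []
    for d in dels:
        fp = flanks_from_reference(ref_str, d.bp5, d.bp3, config.flank_window)
        flank_rows.append(
            {
                "product_id": d.product_id,
                "five_prime_flank": fp.five_prime_flank,
                "three_prime_flank": fp.three_prime_flank,
            }
        )
    return DeletionSet(
        reference=ref_str,
        deletions=dels,
        flanks=pd.DataFrame(flank_rows),
        truth=pd.DataFrame(truth_rows),
    )
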