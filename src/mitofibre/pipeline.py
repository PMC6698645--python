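"""Orchestration: bundled reference tables, schema checks, end-to-end runs.

Two published single-fibre tables ship with the package as versioned CSV
fixtures so every downstream computation is reproducible offline:

* ``deletion_products.csv`` — 30 sequenced mtDNA deletion products from 21
  laser-microdissected muscle fibres of four mtDNA maintenance-disorder
  patients: breakpoints (rCRS), sizes, per-cell triplex metrics, retained
  junction flank sequences and the published repeat annotation.
* ``smpcr_fibres.csv`` — 79 single-fibre limiting-dilution smPCR summaries
  from three patients: deletion count per fibre, species sizes (kb) and
  positive-well proportions, plus the published largest-deletion call.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import clonalsim, ifquant, smpcr, synthdata, triplex
from .breakpoints import call_repeats
from .mtgenome import DeletionEvent, annotate_table, load_genome_map

log = logging.getLogger("mitofibre")

_CHECKSUMS = {
    "deletion_products.csv":
        "84dcf8f6c7a1d317912d01aa68a804ef15bfe2bd7f75303afc1cdabf9790dcbe",
    "smpcr_fibres.csv":
        "59470b5d55da5c1b40b93902670bf05d8489a9043de6757139bc59d92ea63328",
}


class FixtureError(ValueError):
    pass


def _fixture_path(name: str) -> Path:
    return Path(str(resources.files("mitofibre") / "data" / name))


def load_reference_tables(verify: bool = True) -> dict[str, pd.DataFrame]:
    """Load the bundled reference tables, verifying shape and checksum.

    Returns ``{"deletions": ..., "smpcr": ...}``. The deletion table must
    hold 30 products over 21 cells (the source text's "31 species" claim
    is not supported by its own printed table, whose per-cell counts
    14x1 + 5x2 + 2x3 sum to 30); the smPCR table 26 + 27 + 26 fibres for
    patients P7, P8 and P16.
    """
    frames: dict[str, pd.DataFrame] = {}
    for key, name in (("deletions", "deletion_products.csv"),
                      ("smpcr", "smpcr_fibres.csv")):
        path = _fixture_path(name)
        if verify:
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
            if digest != _CHECKSUMS[name]:
                raise FixtureError(
                    f"{name}: checksum mismatch (file tampered or corrupted)"
                )
        frames[key] = pd.read_csv(path)

    dels = frames["deletions"]
    if len(dels) != 30 or dels["cell_id"].nunique() != 21:
        raise FixtureError(
            f"deletion fixture: expected 30 products over 21 cells, got "
            f"{len(dels)} over {dels['cell_id'].nunique()}"
        )
    sm = frames["smpcr"]
    counts = sm.groupby("patient_id").size().to_dict()
    if counts != {"P7": 26, "P8": 27, "P16": 26}:
        raise FixtureError(f"smPCR fixture: unexpected per-patient rows {counts}")
    return frames


@dataclass(frozen=True)
class RunConfig:
    """End-to-end run configuration (synthetic cohort by default)."""

    out_dir: Path
    seed: int
    synth: synthdata.SynthConfig = field(default=None)  # type: ignore[assignment]
    stages: tuple[str, ...] = ("ifquant", "triplex", "breakpoints", "smpcr", "clonalsim")
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.synth is None:
            object.__setattr__(self, "synth", synthdata.SynthConfig(seed=self.seed))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        synth = synthdata.SynthConfig(seed=int(d["seed"]), **d.get("synth", {}))
        return cls(
            out_dir=Path(d["out_dir"]),
            seed=int(d["seed"]),
            synth=synth,
            stages=tuple(d.get("stages", cls.stages)),
            log_level=str(d.get("log_level", "INFO")),
        )


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages on a synthetic cohort; write a manifest.

    Outputs are sorted CSVs, deterministic for a fixed seed, so reruns
    with the same config are byte-identical. Returns the manifest dict
    (also written as ``manifest.json``).
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config.synth
    outputs: dict[str, str] = {}

    def _write(name: str, df: pd.DataFrame) -> None:
        path = out / name
        df.to_csv(path, index=False)
        outputs[name] = _checksum(path)
        log.info("wrote %s (%d rows)", path, len(df))

    if "ifquant" in config.stages:
        cohort = synthdata.gen_if_cohort(cfg)
        classified = ifquant.classify_cohort(cohort.patients, cohort.controls)
        _write("if_classified.csv", classified.sort_values("fibre_id"))
        summaries = ifquant.summarize_cohort(classified)
        _write("if_summary_mrc.csv", summaries["mrc"])

    if "triplex" in config.stages:
        tp = synthdata.gen_triplex_plate(cfg)
        results = triplex.quantify_plate(tp.plate, tp.standards)
        _write("triplex_results.csv", results.sort_values("fibre_id"))

    if "breakpoints" in config.stages:
        ds = synthdata.gen_deletion_set(cfg)
        gmap = load_genome_map()
        ann = annotate_table(ds.deletions, gmap)
        calls = call_repeats(ds.flanks)
        _write("deletion_annotations.csv", ann.merge(calls, on="product_id"))

    if "smpcr" in config.stages:
        wells = synthdata.gen_smpcr_plates(cfg)
        counts = synthdata.wells_to_counts(wells)
        summary = smpcr.species_proportions("cell1", counts, "synthetic")
        rows = pd.DataFrame(
            [
                {
                    "cell_id": summary.cell_id,
                    "size_kb": s.size_kb,
                    "positive_wells": s.count,
                    "proportion": s.proportion,
                    "ci_low": s.ci[0],
                    "ci_high": s.ci[1],
                }
                for s in summary.species
            ]
        )
        _write("smpcr_proportions.csv", rows)

    if "clonalsim" in config.stages:
        sim = clonalsim.simulate_cohort(
            clonalsim.SimConfig(
                species=(
                    clonalsim.SpeciesSpec("del_large", 8.0, 100),
                    clonalsim.SpeciesSpec("del_small", 12.0, 100),
                ),
                alpha=0.0,
                n_steps=2_000,
                n_cells=500,
                seed=config.seed,
            )
        )
        _write("clonalsim_quantiles.csv", sim.heteroplasmy_quantiles)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "outputs": outputs,
        "config": {
            "out_dir": str(config.out_dir),
            "synth": {k: v for k, v in vars(cfg).items()},
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def fixture_deletion_events(dels: pd.DataFrame) -> list[DeletionEvent]:
    """DeletionEvent objects from the bundled deletion table."""
    return [
        DeletionEvent(str(r.cell_id), str(r.product_id), int(r.bp5), int(r.bp3))
        for r in dels.itertuples(index=False)
    ]
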