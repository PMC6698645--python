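"""Stochastic clonal expansion of mtDNA species within single cells.

Two hypotheses for how deleted mtDNA expands inside a post-mitotic cell:
random genetic drift under relaxed replication, and "survival of the
smallest" (shorter genomes replicate faster). Both are expressed here as
a Moran process: the cell holds a fixed number N of mtDNA molecules; at
each event one molecule chosen uniformly is degraded and one molecule
chosen with probability proportional to count_i * w_i is replicated,
with replication weight

    w_i = (L_wt / L_i) ** alpha

so alpha = 0 is exact neutrality (pure drift) and alpha = 1 makes the
replication rate inversely proportional to genome length. Birth and death
are drawn independently from the same pre-event state. The summary
statistic mirrors the single-molecule PCR readout: among multi-species
cells, the fraction in which the smallest genome (largest deletion) is
strictly most prevalent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

WILD_TYPE_LENGTH_KB = 16.6


class SimError(ValueError):
    pass


@dataclass(frozen=True)
class SpeciesSpec:
    label: str
    genome_length_kb: float
    initial_copies: int

    def __post_init__(self) -> None:
        if not 0 < self.genome_length_kb <= WILD_TYPE_LENGTH_KB:
            raise SimError(
                f"{self.label}: genome length {self.genome_length_kb} kb "
                f"outside (0, {WILD_TYPE_LENGTH_KB}]"
            )
        if self.initial_copies < 0:
            raise SimError(f"{self.label}: negative initial copies")


@dataclass(frozen=True)
class SimConfig:
    species: tuple[SpeciesSpec, ...]
    alpha: float = 0.0
    n_steps: int = 10_000
    n_cells: int = 1
    seed: int = 0
    record_times: tuple[int, ...] = ()
    #: evaluate prevalence among all species (True) or deleted species only
    include_wild_type: bool = False
    #: optional per-replication probability that the copy acquires a new
    #: deletion, turning into the next smaller species (off by default)
    formation_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise SimError(f"alpha must be >= 0, got {self.alpha}")
        if not self.species:
            raise SimError("no species defined")
        if self.total_copies <= 1:
            raise SimError("total copy number must exceed 1")
        if not 0 <= self.formation_prob < 1:
            raise SimError("formation_prob outside [0, 1)")

    @property
    def total_copies(self) -> int:
        return sum(s.initial_copies for s in self.species)

    def weights(self) -> np.ndarray:
        lengths = np.array([s.genome_length_kb for s in self.species])
        return (WILD_TYPE_LENGTH_KB / lengths) ** self.alpha


def moran_step(
    state: np.ndarray, weights: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One Moran event: uniform death, weight-biased birth, N conserved."""
    state = np.asarray(state)
    n = int(state.sum())
    if n <= 1:
        raise SimError("Moran step needs total copy number > 1")
    death_p = state / n
    birth_p = state * weights
    birth_p = birth_p / birth_p.sum()
    death = rng.choice(len(state), p=death_p)
    birth = rng.choice(len(state), p=birth_p)
    new = state.copy()
    new[death] -= 1
    new[birth] += 1
    return new


def simulate_cell(config: SimConfig) -> pd.DataFrame:
    """Trajectory of one cell; rows are (step, per-species counts).

    Deterministic for a fixed seed. ``record_times`` default to the final
    step only.
    """
    rng = np.random.default_rng(config.seed)
    state = np.array([s.initial_copies for s in config.species], dtype=np.int64)
    weights = config.weights()
    record = set(config.record_times) or {config.n_steps}
    labels = [s.label for s in config.species]
    rows = []
    if 0 in record:
        rows.append({"step": 0, **dict(zip(labels, state))})
    for step in range(1, config.n_steps + 1):
        state = moran_step(state, weights, rng)
        if step in record:
            rows.append({"step": step, **dict(zip(labels, state))})
    if not rows or rows[-1]["step"] != config.n_steps:
        rows.append({"step": config.n_steps, **dict(zip(labels, state))})
    return pd.DataFrame(rows)


def _simulate_states(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Final states of all cells, vectorised across cells.

    Every cell starts from the same initial state and evolves
    independently; each loop iteration applies one Moran event to every
    cell at once (same kernel as :func:`moran_step`).
    """
    n_cells, n_sp = config.n_cells, len(config.species)
    n = config.total_copies
    weights = config.weights()
    counts = np.tile(
        np.array([s.initial_copies for s in config.species], dtype=np.int64),
        (n_cells, 1),
    )
    idx = np.arange(n_cells)
    for _ in range(config.n_steps):
        u_death = rng.random((n_cells, 1))
        u_birth = rng.random((n_cells, 1))
        cum_d = np.cumsum(counts, axis=1) / n
        death = (u_death > cum_d[:, :-1]).sum(axis=1) if n_sp > 1 else np.zeros(
            n_cells, dtype=np.int64
        )
        w = counts * weights
        cum_b = np.cumsum(w, axis=1)
        cum_b /= cum_b[:, -1:]
        birth = (u_birth > cum_b[:, :-1]).sum(axis=1) if n_sp > 1 else np.zeros(
            n_cells, dtype=np.int64
        )
        counts[idx, death] -= 1
        if config.formation_prob > 0 and n_sp > 1:
            mutate = rng.random(n_cells) < config.formation_prob
            birth = np.where(
                mutate & (birth < n_sp - 1), birth + 1, birth
            )
        counts[idx, birth] += 1
    return counts


@dataclass(frozen=True)
class SimSummary:
    config: SimConfig
    final_states: pd.DataFrame
    heteroplasmy_quantiles: pd.DataFrame
    n_multi_species_cells: int
    smallest_most_prevalent_fraction: float
    fixation_counts: dict[str, int]
    loss_counts: dict[str, int]


def summarize_states(config: SimConfig, counts: np.ndarray) -> SimSummary:
    labels = [s.label for s in config.species]
    lengths = np.array([s.genome_length_kb for s in config.species])
    n = config.total_copies

    if config.include_wild_type:
        mask = np.ones(len(labels), dtype=bool)
    else:
        mask = lengths < WILD_TYPE_LENGTH_KB
        if not mask.any():
            mask = np.ones(len(labels), dtype=bool)
    sub = counts[:, mask]
    sub_lengths = lengths[mask]

    multi = (sub > 0).sum(axis=1) >= 2
    n_multi = int(multi.sum())
    smallest_idx = int(np.argmin(sub_lengths))
    if n_multi:
        m = sub[multi]
        top = m.max(axis=1)
        strict = (m[:, smallest_idx] == top) & (
            (m == top[:, None]).sum(axis=1) == 1
        )
        frac = float(strict.mean())
    else:
        frac = math.nan

    quants = []
    for j, lab in enumerate(labels):
        h = counts[:, j] / n
        q = np.quantile(h, [0.05, 0.25, 0.5, 0.75, 0.95])
        quants.append(
            {
                "species": lab,
                "mean": float(h.mean()),
                "q05": q[0], "q25": q[1], "median": q[2], "q75": q[3], "q95": q[4],
            }
        )
    fixation = {lab: int((counts[:, j] == n).sum()) for j, lab in enumerate(labels)}
    loss = {lab: int((counts[:, j] == 0).sum()) for j, lab in enumerate(labels)}
    return SimSummary(
        config=config,
        final_states=pd.DataFrame(counts, columns=labels),
        heteroplasmy_quantiles=pd.DataFrame(quants),
        n_multi_species_cells=n_multi,
        smallest_most_prevalent_fraction=frac,
        fixation_counts=fixation,
        loss_counts=loss,
    )


def simulate_cohort(config: SimConfig) -> SimSummary:
    """Simulate n_cells independent cells and summarise the endpoint.

    Reports the smPCR-comparable statistic: among cells where >= 2
    species survive, the fraction in which the smallest genome is
    strictly most prevalent.
    """
    if config.n_cells < 1:
        raise SimError("n_cells must be >= 1")
    rng = np.random.default_rng(config.seed)
    counts = _simulate_states(config, rng)
    return summarize_states(config, counts)


def compare_to_observed(
    summary: SimSummary | float, observed_numerator: int, observed_denominator: int
) -> float:
    """Exact two-sided binomial probability of the observed prevalence count
    under the simulated smallest-most-prevalent fraction."""
    if observed_denominator < 1:
        raise SimError("observed denominator must be >= 1")
    if observed_numerator > observed_denominator:
        raise SimError("observed numerator exceeds denominator")
    p = (
        summary.smallest_most_prevalent_fraction
        if isinstance(summary, SimSummary)
        else float(summary)
    )
    if math.isnan(p):
        raise SimError("simulated fraction undefined (no multi-species cells)")
    return float(
        stats.binomtest(observed_numerator, observed_denominator, p).pvalue
    )


def config_from_dict(d: dict) -> SimConfig:
    """Build a SimConfig from a parsed YAML/JSON mapping."""
    species = tuple(
        SpeciesSpec(
            label=str(s["label"]),
            genome_length_kb=float(s["genome_length_kb"]),
            initial_copies=int(s["initial_copies"]),
        )
        for s in d["species"]
    )
    return SimConfig(
        species=species,
        alpha=float(d.get("alpha", 0.0)),
        n_steps=int(d.get("n_steps", 10_000)),
        n_cells=int(d.get("n_cells", 1)),
        seed=int(d["seed"]),
        record_times=tuple(d.get("record_times", ())),
        include_wild_type=bool(d.get("include_wild_type", False)),
        formation_prob=float(d.get("formation_prob", 0.0)),
    )
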