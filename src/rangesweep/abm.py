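"""Two-dimensional deme-based agent-based model (spatial Moran process).

Individuals live in well-mixed demes of carrying capacity ``K`` on a square
lattice, initially filled with a resident population; a single wildtype
invader is introduced at the central deme.  Each event replaces a
fitness-weighted random individual by two offspring, each of which migrates
with probability ``m`` to one of four neighbouring demes; a deme pushed over
its capacity immediately loses uniformly chosen individuals.  Mutation is
coupled to wildtype reproduction (and, when more than one mutation may
accumulate, to all invader reproduction).  Residents never disperse.

Lengths are measured in "cell diameters" — the side of the unit area one
individual occupies — so the effective radius of a clade of N individuals
is ``sqrt(N/pi)`` and a deme of capacity K is ``sqrt(K)`` cell diameters
wide.  One generation is the mean division time of a rate-1 individual.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import _abm_kernels as _k

__all__ = [
    "SimConfig",
    "SimOutcome",
    "SpeedEstimate",
    "run_simulation",
    "measure_expansion_speed",
    "moran_survival_probability",
    "empirical_moran_survival",
    "draw_mutation_effect",
    "effective_radius",
    "detect_sweep",
    "record_first_survivor",
]

_STOP_REASONS = {
    _k.OK_SIZE: "size",
    _k.OK_TIME: "time",
    _k.EXTINCT: "extinct",
}


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one agent-based run (defaults: the validation set).

    ``effect_mode='fixed'`` gives every mutation proliferation rate ``r_m``;
    ``'random'`` draws multiplicative effects with diminishing returns
    towards the maximum birth rate ``M`` (mean effect parameter ``s``).
    """

    K: int = 16
    m: float = 0.05
    mu_tilde: float = 1e-5
    r_re: float = 0.91
    r_wt: float = 1.0
    effect_mode: str = "fixed"
    r_m: float = 1.3
    s: float = 0.1
    M: float = 10.0
    max_mutations: int = 1          # 0 means unlimited
    stop_N: int = 1_000_000
    stop_generations: float = 2000.0
    sweep_stringency: float = 1.0
    grid_extent: int | None = None  # lattice half-width in demes; None: auto
    genotype_capacity: int = 200_000

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be at least 1")
        if not 0 <= self.m <= 1:
            raise ValueError("m must lie in [0, 1]")
        if self.mu_tilde < 0:
            raise ValueError("mu_tilde must be non-negative")
        if self.effect_mode not in ("fixed", "random"):
            raise ValueError("effect_mode must be 'fixed' or 'random'")
        if self.effect_mode == "fixed" and not (self.r_m > self.r_wt > self.r_re > 0):
            raise ValueError("require r_m > r_wt > r_re > 0")
        if self.effect_mode == "random" and self.M <= self.r_wt:
            raise ValueError("maximum birth rate M must exceed r_wt")
        if not 0 < self.sweep_stringency <= 1:
            raise ValueError("sweep_stringency must lie in (0, 1]")
        if self.stop_N <= 0 or self.stop_generations <= 0:
            raise ValueError("stop criteria must be positive")

    @property
    def deme_width(self) -> float:
        """Deme width in cell diameters, sqrt(K)."""
        return math.sqrt(self.K)

    def auto_grid_side(self) -> int:
        """Lattice side large enough to contain the expansion before stopping.

        The ragged front lets the furthest occupied deme outrun the bulk
        effective radius, so a generous relative margin is applied.
        """
        if self.grid_extent is not None:
            return 2 * self.grid_extent + 1
        max_radius_demes = math.sqrt(self.stop_N / math.pi) / self.deme_width
        half = int(math.ceil(1.35 * max_radius_demes)) + 8
        return 2 * half + 1


@dataclass(frozen=True)
class SimOutcome:
    """Per-replicate result of :func:`run_simulation`."""

    sweep: bool
    sweep_radius: float          # effective radius when the sweep completed (nan if none)
    first_survivor_radius: float  # clade radius when the first surviving mutant was born
    first_survivor_distance: float  # its origin deme's distance from the centre (cells)
    n_sweeps: int
    stop_reason: str
    final_N: int
    final_time: float
    n_mutations: int
    genotypes: pd.DataFrame = field(repr=False)


@dataclass(frozen=True)
class SpeedEstimate:
    """Radial expansion speed from replicate regressions."""

    c: float                      # mean slope, cell diameters / generation
    slopes: tuple
    relative_sd: float
    n_excluded: int               # extinct replicates that were resampled


def effective_radius(N) -> float:
    """sqrt(N / pi): radius of a disc holding N individuals at unit density."""
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        raise ValueError("N must be non-negative")
    out = np.sqrt(N / np.pi)
    return out if out.shape else float(out)


def moran_survival_probability(r_wt: float, r_m: float, K: int) -> float:
    """Fixation probability of one mutant in a K-individual Moran deme.

    ``rho = (1 - r_wt/r_m) / (1 - (r_wt/r_m)^K)``; the limit as
    ``r_m -> r_wt`` is the neutral value ``1/K``.  For small migration
    probability this approximates the probability that a new mutant survives
    genetic drift in the spatial model.
    """
    if r_wt <= 0 or r_m <= 0:
        raise ValueError("rates must be positive")
    if K < 1:
        raise ValueError("K must be at least 1")
    ratio = r_wt / r_m
    if abs(1.0 - ratio) < 1e-12:
        return 1.0 / K
    return (1.0 - ratio) / (1.0 - ratio**K)


def empirical_moran_survival(
    r_wt: float, r_m: float, K: int, n_runs: int, seed: int
) -> tuple[float, float]:
    """(fixation frequency, binomial SE) from single-deme simulations."""
    n_fixed = _k.moran_fixation_runs(K, r_wt, r_m, n_runs, seed % 2**31)
    p = n_fixed / n_runs
    return p, math.sqrt(max(p * (1 - p), 1e-12) / n_runs)


def draw_mutation_effect(r_parent: float, s: float, M: float, rng: np.random.Generator) -> float:
    """Child proliferation rate under diminishing-returns epistasis.

    ``r_child = min(r_parent (1 + s X (1 - r_parent/M)), M)`` with
    ``X ~ Exp(1)``, so small-effect mutations scale multiplicatively with
    mean relative effect ``s (1 - r_parent/M)`` and rates never exceed M.
    """
    if not 0 < r_parent <= M:
        raise ValueError("require 0 < r_parent <= M")
    if s <= 0:
        raise ValueError("s must be positive")
    x = rng.exponential(1.0)
    return min(r_parent * (1.0 + s * x * (1.0 - r_parent / M)), M)


def _kernel_args(config: SimConfig, seed: int, *, rec_dt: float = 0.0) -> tuple:
    G = config.auto_grid_side()
    max_mut = config.max_mutations if config.max_mutations > 0 else 2**30
    return (
        G,
        config.K,
        config.m,
        config.mu_tilde,
        config.r_re,
        0,  # residents never migrate
        config.r_wt,
        0 if config.effect_mode == "fixed" else 1,
        config.r_m,
        config.s,
        config.M,
        max_mut,
        1 if config.max_mutations == 1 else 0,
        config.stop_N,
        config.stop_generations,
        config.sweep_stringency,
        config.genotype_capacity,
        rec_dt,
        seed % 2**31,
    )


def _genotype_frame(res) -> pd.DataFrame:
    (rate, parent, nmut, count, maxcount, birth_t, birth_dist, birth_cladeN) = res[8:16]
    return pd.DataFrame(
        {
            "rate": rate,
            "parent": parent,
            "n_mutations": nmut,
            "count": count,
            "max_count": maxcount,
            "birth_time": birth_t,
            "birth_deme_distance": birth_dist,
            "birth_clade_N": birth_cladeN,
        }
    )


def run_simulation(config: SimConfig, seed: int) -> SimOutcome:
    """Run one replicate; raises on resource errors with advice."""
    res = _k.run_abm(*_kernel_args(config, seed))
    status = res[0]
    if status == _k.ERR_EDGE:
        raise RuntimeError(
            "expansion reached the lattice boundary before a stop criterion; "
            "increase grid_extent"
        )
    if status == _k.ERR_GENO_CAP:
        raise RuntimeError("genotype table exhausted; increase genotype_capacity")
    if status == _k.ERR_SLOTS:
        raise RuntimeError("too many coexisting genotypes in one deme")
    genotypes = _genotype_frame(res)
    first_radius, first_dist = record_first_survivor(genotypes, deme_width=config.deme_width)
    return SimOutcome(
        sweep=bool(res[4]),
        sweep_radius=float(res[5]) if res[5] > 0 else float("nan"),
        first_survivor_radius=first_radius,
        first_survivor_distance=first_dist,
        n_sweeps=int(res[6]),
        stop_reason=_STOP_REASONS.get(status, str(status)),
        final_N=int(res[2]),
        final_time=float(res[1]),
        n_mutations=int(res[7]) - 2,
        genotypes=genotypes,
    )


def record_first_survivor(
    genotypes: pd.DataFrame, survival_abundance: int = 10, deme_width: float = 4.0
) -> tuple[float, float]:
    """Birth radius and origin distance of the earliest surviving mutant.

    A mutant lineage "survives" if its abundance ever reached
    ``survival_abundance`` individuals.  Returns (clade effective radius at
    its birth, origin-deme distance from the centre in cell diameters), or
    (nan, nan) if no lineage qualifies.
    """
    mutants = genotypes.iloc[2:]
    surv = mutants[mutants["max_count"] >= survival_abundance]
    if surv.empty:
        return float("nan"), float("nan")
    first = surv.loc[surv["birth_time"].idxmin()]
    return (
        effective_radius(first["birth_clade_N"]),
        float(first["birth_deme_distance"]) * deme_width,
    )


def detect_sweep(genotypes: pd.DataFrame, stringency: float = 1.0) -> bool:
    """Whether any single mutation is carried by >= stringency of the clade.

    Carrier counts are subtree sums over the lineage tree (a genotype
    carries all mutations of its ancestors).
    """
    if not 0 < stringency <= 1:
        raise ValueError("stringency must lie in (0, 1]")
    counts = genotypes["count"].to_numpy().copy()
    parents = genotypes["parent"].to_numpy()
    clade_N = counts[1:].sum()
    if clade_N == 0:
        return False
    for gid in range(len(counts) - 1, 1, -1):
        if parents[gid] >= 1:
            counts[parents[gid]] += counts[gid]
    return bool(np.any(counts[2:] >= math.ceil(stringency * clade_N)))


def measure_expansion_speed(
    config: SimConfig,
    *,
    invader: str = "wildtype",
    max_radius_cells: float = 160.0,
    fit_from_radius_cells: float | None = None,
    replicates: int = 10,
    seed: int = 0,
    rec_dt: float = 1.0,
) -> SpeedEstimate:
    """Radial expansion speed by linear regression of sqrt(N/pi) on time.

    ``invader='wildtype'`` seeds a wildtype into the resident background;
    ``invader='mutant'`` seeds a rate-``r_m`` mutant into a wildtype
    background (which, unlike residents, disperses).  Mutation is disabled.
    The regression discards the transient before the effective radius
    reaches ``fit_from_radius_cells`` (default: 10 deme widths) and each
    extinct replicate is excluded and resampled with a fresh seed.
    """
    if invader == "wildtype":
        bg_r, inv_r, bg_migrates = config.r_re, config.r_wt, 0
    elif invader == "mutant":
        bg_r, inv_r, bg_migrates = config.r_wt, config.r_m, 1
    else:
        raise ValueError("invader must be 'wildtype' or 'mutant'")
    if fit_from_radius_cells is None:
        fit_from_radius_cells = 10.0 * config.deme_width

    stop_N = int(math.pi * max_radius_cells**2)
    # the raggedness of the front lets the furthest occupied deme outrun the
    # bulk effective radius, so leave a generous margin
    r_demes = max_radius_cells / config.deme_width
    half = int(math.ceil(1.3 * r_demes)) + 8
    G = 2 * half + 1
    stop_gens = 20.0 + 3.0 * max_radius_cells / _fkpp_speed_guess(bg_r, inv_r, config)

    slopes: list[float] = []
    n_excluded = 0
    attempt = 0
    while len(slopes) < replicates:
        run_seed = (seed * 1_000_003 + attempt * 7919 + 1) % 2**31
        attempt += 1
        if attempt > 60 * replicates:
            raise RuntimeError("invader went extinct in almost every replicate")
        res = _k.run_abm(
            G, config.K, config.m, 0.0, bg_r, bg_migrates, inv_r,
            0, inv_r, 0.0, 10.0, 1, 1,
            stop_N, stop_gens, 1.0, 16, rec_dt, run_seed,
        )
        status, traj = res[0], res[16]
        if status == _k.EXTINCT:
            n_excluded += 1
            continue
        if status == _k.ERR_EDGE:
            raise RuntimeError("front reached the lattice edge; enlarge the grid")
        times = np.arange(len(traj)) * rec_dt
        radii = effective_radius(traj)
        mask = radii >= fit_from_radius_cells
        if mask.sum() < 10:
            raise RuntimeError(
                "trajectory too short for regression; increase max_radius_cells"
            )
        slope = np.polyfit(times[mask], radii[mask], 1)[0]
        slopes.append(float(slope))

    arr = np.asarray(slopes)
    return SpeedEstimate(
        c=float(arr.mean()),
        slopes=tuple(slopes),
        relative_sd=float(arr.std(ddof=1) / arr.mean()),
        n_excluded=n_excluded,
    )


def _fkpp_speed_guess(bg_r: float, inv_r: float, config: SimConfig) -> float:
    """Crude lower bound on the expansion speed, used only to size the
    time-stop so the simulation always terminates via the radius stop."""
    a = max(inv_r - bg_r, 1e-3)
    d_coeff = config.m * config.K / 4.0
    return max(0.25 * 2.0 * math.sqrt(a * d_coeff), 0.02)


def run_batch(
    config: SimConfig,
    n_replicates: int,
    seed: int,
    *,
    condition_on_establishment: bool = True,
) -> list[SimOutcome]:
    """Independent replicates with seeds spawned from one master seed.

    By default, replicates in which the founding wildtype lineage dies out
    (which happens in the vast majority of attempts, since its drift
    survival probability is only ~0.1 at the default rates) are discarded
    and resampled, so that sweep frequencies refer to established range
    expansions — the situation the macroscopic model describes.
    """
    ss = np.random.SeedSequence(seed)
    outcomes: list[SimOutcome] = []
    chunk = 0
    while len(outcomes) < n_replicates:
        chunk += 1
        if chunk > 80:
            raise RuntimeError("wildtype failed to establish in almost every attempt")
        for child in ss.spawn(4 * n_replicates):
            out = run_simulation(config, int(child.generate_state(1)[0] % 2**31))
            if out.stop_reason == "extinct" and condition_on_establishment:
                continue
            outcomes.append(out)
            if len(outcomes) == n_replicates:
                break
    return outcomes
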