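"""Two-proportion Z tests and the two-scenario power procedure.

Within a population, the count of a given mutation type among its private
segregating alleles is treated as binomial: successes out of ``trials``
total private alleles.  Two populations are compared with the pooled
two-proportion Z statistic

    Z = (p2 - p1) / sqrt(p* (1 - p*) (1/n1 + 1/n2)),
    p* = (n1 p1 + n2 p2) / (n1 + n2),

where the n are trial counts.  Because the population carrying a rate shift
is unknown in real data, power for a fold-``f`` shift of one mutation type
is evaluated under two scenarios — the shift placed in population 1 or in
population 2 — and the minimum of the two scenario averages is reported.
Under a Jukes-Cantor baseline the expected share of each type is 1/c
(c = 96 strand-collapsed by default, or 192), and a fold-f shift moves the
shifted population's share to f/(c - 1 + f).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .demography import PopulationModel
from .mutation_model import (
    MutationRateMatrix,
    MutationType,
    apply_fold_shift,
    build_uniform_matrix,
    normalize_overall_rate,
    type_index,
)
from .sequence import AncestralSequence, generate_sequence
from .simulator import simulate_dataset
from .spectra import COLLAPSE_MAP, COLLAPSED_96, STRANDED_192, _revcomp_type, private_segregating

__all__ = [
    "BinomialCount",
    "PowerResult",
    "pooled_proportion",
    "z_statistic",
    "analytic_power",
    "scenario_power",
    "min_scenario_power",
    "power_surface",
    "load_relative_rates",
]

#: Overall per-site per-generation mutation rate used throughout.
DEFAULT_MU = 1e-8


def load_relative_rates() -> pd.DataFrame:
    """The shipped table of approximate single-type fold shifts for human
    populations (columns population / mutation_type / fold / strength)."""
    from importlib import resources

    path = resources.files("mutspectra") / "data" / "shifts" / "human_relative_rates.tsv"
    return pd.read_csv(str(path), sep="\t", comment="#")

DEFAULT_ALPHA = 0.05


class BinomialCount(NamedTuple):
    """Successes (focal-type private alleles) out of trials (all private
    segregating alleles) in one population."""

    successes: int
    trials: int

    @property
    def proportion(self) -> float:
        if self.trials == 0:
            raise ZeroDivisionError("proportion undefined with zero trials")
        return self.successes / self.trials


def _check_count(x: BinomialCount) -> BinomialCount:
    x = BinomialCount(*x)
    if not 0 <= x.successes <= x.trials:
        raise ValueError(f"invalid binomial count {x}")
    return x


def pooled_proportion(x1: BinomialCount, x2: BinomialCount) -> float:
    """p* of the pooled sample: total successes / total trials."""
    x1, x2 = _check_count(x1), _check_count(x2)
    total = x1.trials + x2.trials
    if total == 0:
        raise ValueError("both samples have zero trials")
    return (x1.successes + x2.successes) / total


def z_statistic(x1: BinomialCount, x2: BinomialCount) -> float:
    """The pooled two-proportion Z statistic (antisymmetric in its
    arguments; undefined when the pooled proportion is 0 or 1)."""
    x1, x2 = _check_count(x1), _check_count(x2)
    if x1.trials == 0 or x2.trials == 0:
        raise ValueError("both samples need at least one trial")
    p_star = pooled_proportion(x1, x2)
    if p_star in (0.0, 1.0):
        raise ValueError(f"degenerate pooled proportion {p_star}")
    se = math.sqrt(p_star * (1.0 - p_star) * (1.0 / x1.trials + 1.0 / x2.trials))
    return (x2.proportion - x1.proportion) / se


def analytic_power(
    p1: float, p2: float, n1: int, n2: int, alpha: float = DEFAULT_ALPHA
) -> float:
    """Normal-approximation probability that the two-tailed pooled Z test at
    level ``alpha`` rejects when the true proportions are (p1, p2) with
    (n1, n2) trials.

    The rejection region uses the pooled null standard error; under the
    alternative the difference estimator has its own (unpooled) standard
    error — the standard two-sample-proportion power approximation.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    for p in (p1, p2):
        if not (0.0 < p < 1.0):
            raise ValueError("proportions must lie strictly in (0, 1)")
    if n1 < 1 or n2 < 1:
        raise ValueError("trial counts must be positive")
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    p_bar = (n1 * p1 + n2 * p2) / (n1 + n2)
    se0 = math.sqrt(p_bar * (1.0 - p_bar) * (1.0 / n1 + 1.0 / n2))
    se1 = math.sqrt(p1 * (1.0 - p1) / n1 + p2 * (1.0 - p2) / n2)
    delta = p2 - p1
    upper = stats.norm.sf((z_crit * se0 - delta) / se1)
    lower = stats.norm.cdf((-z_crit * se0 - delta) / se1)
    return float(upper + lower)


@dataclass(frozen=True)
class PowerResult:
    """Power for one (pair, type, fold, sizes, scenario) cell."""

    population_pair: tuple
    mutation_type: MutationType
    fold: float
    n1: int
    n2: int
    scenario: str  # "shift_in_pop1" | "shift_in_pop2"
    power: float
    replicates: int
    alpha: float = DEFAULT_ALPHA
    mean_trials: tuple = (np.nan, np.nan)

    def __post_init__(self):
        if not (0.0 <= self.power <= 1.0) and not math.isnan(self.power):
            raise ValueError(f"power {self.power} outside [0, 1]")


# ---------------------------------------------------------------------------
# simulation-backed power


def _type_count_96(table, pop: str, focal_96: int) -> BinomialCount:
    priv = private_segregating(table, pop)
    idx96 = COLLAPSE_MAP[priv.type_indices()]
    return BinomialCount(int(np.sum(idx96 == focal_96)), len(priv))


def _focal_indices(mutation_type: MutationType, space: str):
    """Stranded-192 indices covered by the focal category, and its
    category id in the working space."""
    i = type_index(mutation_type)
    if space == STRANDED_192:
        return [i], i
    if space == COLLAPSED_96:
        j = type_index(_revcomp_type(mutation_type))
        cat = int(COLLAPSE_MAP[i])
        return sorted({i, j}), cat
    raise ValueError(f"unknown spectrum space {space!r}")


def _shifted_matrix(
    base: MutationRateMatrix,
    mutation_type: MutationType,
    fold: float,
    seq: AncestralSequence,
    space: str,
    mu: float,
    renormalize: bool,
) -> MutationRateMatrix:
    """Fold-shift the focal type (both strand representatives when working
    strand-collapsed: a biological rate change affects the pair) and
    renormalize so the overall rate stays at ``mu``."""
    m = apply_fold_shift(base, mutation_type, fold)
    if space == COLLAPSED_96:
        partner = _revcomp_type(mutation_type)
        if type_index(partner) != type_index(mutation_type):
            m = apply_fold_shift(m, partner, fold)
    if renormalize:
        m = normalize_overall_rate(m, seq, mu)
    elif not m.normalized:
        m = MutationRateMatrix(m.rates, overall_rate=base.overall_rate)
    return m


def _expected_share(matrix: MutationRateMatrix, seq: AncestralSequence, flat_idx, space: str) -> float:
    from .mutation_model import expected_type_proportions

    props = expected_type_proportions(matrix, seq)
    return float(props[flat_idx].sum())


def scenario_power(
    model: PopulationModel,
    population_pair: tuple,
    mutation_type: MutationType,
    fold: float,
    n1: int,
    n2: int,
    region_length: int = 1_000_000,
    window_length: int = 10_000,
    replicates: int = 20,
    alpha: float = DEFAULT_ALPHA,
    seed=None,
    space: str = COLLAPSED_96,
    mode: str = "expected",
    seq: Optional[AncestralSequence] = None,
    mu: float = DEFAULT_MU,
    renormalize: bool = True,
) -> tuple:
    """Power under both shift placements for one fold and sample-size pair.

    Per scenario, ``replicates`` independent regions are simulated under the
    demographic model with a Jukes-Cantor matrix carrying the fold shift in
    the shifted population only; each region yields per-population private
    allele counts.  In ``expected`` mode (the default, matching the 1/c
    normality treatment) power is computed analytically from the expected
    type shares with the realized trial counts, then averaged; in
    ``empirical`` mode the Z test is applied once per region to the realized
    counts and power is the rejection fraction.
    """
    from .pipeline import seed_stream

    if mode not in ("expected", "empirical"):
        raise ValueError(f"unknown mode {mode!r}")
    p1_id, p2_id = population_pair
    if seq is None:
        # uniform-composition synthetic region: every category expects 1/c
        seq = generate_sequence(region_length, (0.25, 0.25, 0.25, 0.25), seed=seed_stream(seed, "seq"))
    base = normalize_overall_rate(build_uniform_matrix(), seq, mu)
    flat_idx, focal_cat = _focal_indices(mutation_type, space)
    shifted = _shifted_matrix(base, mutation_type, fold, seq, space, mu, renormalize)

    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    samples = {p1_id: 2 * int(n1), p2_id: 2 * int(n2)}
    results = []
    for scenario_pop, name in ((p1_id, "shift_in_pop1"), (p2_id, "shift_in_pop2")):
        # unsampled populations (ancestors, migration conduits) mutate at the
        # unshifted baseline
        matrices = {pid: base for pid in model.population_ids}
        matrices[scenario_pop] = shifted
        p_exp = {
            pid: _expected_share(matrices[pid], seq, flat_idx, space)
            for pid in (p1_id, p2_id)
        }
        powers, rejections, trials_log = [], [], []
        for r in range(replicates):
            table = simulate_dataset(
                model, seq, matrices, samples,
                window_length=window_length,
                seed=seed_stream(seed, "power", name, fold, n1, n2, r),
            )
            x1 = _count_in_space(table, p1_id, flat_idx, space)
            x2 = _count_in_space(table, p2_id, flat_idx, space)
            trials_log.append((x1.trials, x2.trials))
            if x1.trials == 0 or x2.trials == 0:
                continue
            if mode == "expected":
                powers.append(analytic_power(p_exp[p1_id], p_exp[p2_id], x1.trials, x2.trials, alpha))
            else:
                try:
                    rejections.append(abs(z_statistic(x1, x2)) > z_crit)
                except ValueError:  # degenerate pooled proportion: no rejection
                    rejections.append(False)
        if mode == "expected":
            power = float(np.mean(powers)) if powers else float("nan")
            used = len(powers)
        else:
            power = float(np.mean(rejections)) if rejections else float("nan")
            used = len(rejections)
        mean_trials = tuple(np.mean(trials_log, axis=0)) if trials_log else (np.nan, np.nan)
        results.append(
            PowerResult(
                population_pair=(p1_id, p2_id),
                mutation_type=mutation_type,
                fold=float(fold),
                n1=int(n1),
                n2=int(n2),
                scenario=name,
                power=power,
                replicates=used,
                alpha=alpha,
                mean_trials=mean_trials,
            )
        )
    return tuple(results)


def _count_in_space(table, pop: str, flat_idx, space: str) -> BinomialCount:
    priv = private_segregating(table, pop)
    if len(priv) == 0:
        return BinomialCount(0, 0)
    idx = priv.type_indices()
    hits = np.isin(idx, flat_idx)
    return BinomialCount(int(hits.sum()), len(priv))


def min_scenario_power(results: Sequence[PowerResult]) -> float:
    """The reported quantity: minimum of the scenario-averaged powers."""
    return float(min(r.power for r in results))


def power_surface(
    model: PopulationModel,
    population_pair: tuple,
    mutation_type: MutationType,
    folds: Sequence[float],
    sizes: Sequence[int],
    region_length: int = 1_000_000,
    window_length: int = 10_000,
    replicates: int = 5,
    alpha: float = DEFAULT_ALPHA,
    seed=None,
    space: str = COLLAPSED_96,
    mode: str = "expected",
    seq: Optional[AncestralSequence] = None,
    mu: float = DEFAULT_MU,
) -> pd.DataFrame:
    """The full folds x sizes grid (both scenarios per cell), reproducible
    given ``seed``.

    In ``expected`` mode with renormalized shifts, the distribution of
    private-allele trial counts is exactly invariant to the fold (the total
    rate is held at ``mu`` and category labels are assigned independently
    per mutation), so one set of baseline simulations per size is shared
    across all folds.  ``empirical`` mode simulates every cell.
    """
    from .pipeline import seed_stream

    if len(list(folds)) == 0 or len(list(sizes)) == 0:
        raise ValueError("folds and sizes must be non-empty")
    if any(s < 2 for s in sizes):
        raise ValueError("smallest admissible diploid sample size is 2")
    p1_id, p2_id = population_pair
    rows = []
    if mode == "expected":
        if seq is None:
            seq = generate_sequence(region_length, (0.25, 0.25, 0.25, 0.25), seed=seed_stream(seed, "seq"))
        base = normalize_overall_rate(build_uniform_matrix(), seq, mu)
        flat_idx, _ = _focal_indices(mutation_type, space)
        for n in sizes:
            trials = []
            for r in range(replicates):
                table = simulate_dataset(
                    model, seq, base, {p1_id: 2 * int(n), p2_id: 2 * int(n)},
                    window_length=window_length,
                    seed=seed_stream(seed, "surface", n, r),
                )
                t1 = len(private_segregating(table, p1_id))
                t2 = len(private_segregating(table, p2_id))
                trials.append((t1, t2))
            for fold in folds:
                shifted = _shifted_matrix(base, mutation_type, fold, seq, space, mu, True)
                p_null = _expected_share(base, seq, flat_idx, space)
                p_shift = _expected_share(shifted, seq, flat_idx, space)
                for scenario, (pa, pb) in (
                    ("shift_in_pop1", (p_shift, p_null)),
                    ("shift_in_pop2", (p_null, p_shift)),
                ):
                    powers = [
                        analytic_power(pa, pb, t1, t2, alpha)
                        for t1, t2 in trials
                        if t1 > 0 and t2 > 0
                    ]
                    rows.append(
                        {
                            "pop1": p1_id, "pop2": p2_id,
                            "mutation_type": mutation_type.label,
                            "fold": float(fold), "n1": int(n), "n2": int(n),
                            "scenario": scenario, "alpha": alpha,
                            "replicates": len(powers),
                            "power": float(np.mean(powers)) if powers else np.nan,
                        }
                    )
    else:
        for n in sizes:
            for fold in folds:
                res = scenario_power(
                    model, population_pair, mutation_type, fold, n, n,
                    region_length=region_length, window_length=window_length,
                    replicates=replicates, alpha=alpha,
                    seed=seed_stream(seed, "surface", n, fold),
                    space=space, mode=mode, seq=seq, mu=mu,
                )
                for r in res:
                    rows.append(
                        {
                            "pop1": p1_id, "pop2": p2_id,
                            "mutation_type": mutation_type.label,
                            "fold": r.fold, "n1": r.n1, "n2": r.n2,
                            "scenario": r.scenario, "alpha": r.alpha,
                            "replicates": r.replicates, "power": r.power,
                        }
                    )
    return pd.DataFrame(rows)
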