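"""Monte-Carlo drivers for design operating characteristics.

Each driver repeats the full pipeline -- simulate a cohort, derive the
requested design's dataset from the shared draws, inject carryover, run the
design's test -- over ``B`` independent replicates and aggregates rejection
fractions with their Monte-Carlo standard errors.

Seeding: a root seed spawns one child stream per replicate (and one child
per grid point for curve drivers), so every replicate is independently
reproducible and, because cohort generation consumes the random stream
identically for every design, passing the same root seed to different
designs reuses the same cohorts (common random numbers -- the shared-data
construction that makes the three designs comparable).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .mixed_inference import FitError, fit_ols, fit_random_intercept_ml, lrt_treatment
from .trial_sim import (
    REPRESENTATIVE,
    SUBPOPULATION,
    SimulationModel,
    apply_carryover,
    extract_design,
    simulate_cohort,
)

__all__ = [
    "OCResult",
    "REComparison",
    "run_oc",
    "power_curve",
    "tau_curve",
    "min_n_for_power",
    "selection_bias_oc",
    "compare_random_effects",
    "oc_results_to_frame",
    "frame_to_oc_results",
]

#: Sample-size grid used throughout the power studies.
DEFAULT_N_GRID = (10, 20, 30, 40, 50, 100, 150, 200)
#: Treatment-effect grid for the power-vs-effect studies.
DEFAULT_TAU_GRID = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 2))


@dataclass
class OCResult:
    """Empirical rejection rate for one (design, scenario, n, tau, gamma, p) cell."""

    design: str
    scenario_id: int | None
    n: int
    tau: float
    gamma: float
    p_representative: float
    n_reps: int
    n_rejected: int
    n_excluded: int
    rejection_rate: float
    mc_se: float

    @staticmethod
    def from_counts(
        design: str,
        scenario_id: int | None,
        n: int,
        tau: float,
        gamma: float,
        p_representative: float,
        n_reps: int,
        n_rejected: int,
        n_excluded: int,
    ) -> "OCResult":
        n_eff = n_reps - n_excluded
        rate = n_rejected / n_eff if n_eff > 0 else float("nan")
        mc_se = float(np.sqrt(rate * (1.0 - rate) / n_eff)) if n_eff > 0 else float("nan")
        return OCResult(
            design=design,
            scenario_id=scenario_id,
            n=n,
            tau=tau,
            gamma=gamma,
            p_representative=p_representative,
            n_reps=n_reps,
            n_rejected=n_rejected,
            n_excluded=n_excluded,
            rejection_rate=rate,
            mc_se=mc_se,
        )


@dataclass
class REComparison:
    """Per-replicate BLUP contrast between sub-population and target patients."""

    design: str
    n_reps: int
    diffs: np.ndarray  # mean BLUP(sub-population) - mean BLUP(representative)

    @property
    def mean_diff(self) -> float:
        return float(np.mean(self.diffs))

    @property
    def se_diff(self) -> float:
        return float(np.std(self.diffs, ddof=1) / np.sqrt(len(self.diffs)))

    @property
    def separation(self) -> float:
        """Fraction of replicates where the sub-population BLUP mean is larger."""
        return float(np.mean(self.diffs > 0))


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _one_replicate(
    model: SimulationModel,
    design: str,
    n: int,
    rng: np.random.Generator,
    adjust_carryover: bool,
    alpha: float,
) -> bool:
    """Simulate, extract, carry over, test; True if the null is rejected."""
    cohort = simulate_cohort(model, n, rng)
    data = extract_design(cohort, design, rng)
    if model.carryover > 0:
        data = apply_carryover(data, model.carryover)
    if design == "rct":
        outcome = fit_ols(data, alpha=alpha)
    else:
        outcome = lrt_treatment(data, adjust_carryover=adjust_carryover, alpha=alpha)
    return outcome.rejected


def run_oc(
    model: SimulationModel,
    design: str,
    n: int,
    B: int,
    seed,
    adjust_carryover: bool = False,
    alpha: float = 0.05,
    scenario_id: int | None = None,
) -> OCResult:
    """Estimate the rejection rate of one design over ``B`` replicate trials.

    The rate is a power estimate when ``model.tau`` differs from the null
    value and a type-I-error estimate at ``tau = 0``.  Replicates whose fit
    fails to converge are excluded from the denominator and counted in
    ``n_excluded``.
    """
    if B < 100:
        raise ValueError(f"need B >= 100 replicates for a stable estimate, got {B}")
    children = _as_seedseq(seed).spawn(B)
    n_rejected = 0
    n_excluded = 0
    for child in children:
        rng = np.random.default_rng(child)
        try:
            if _one_replicate(model, design, n, rng, adjust_carryover, alpha):
                n_rejected += 1
        except FitError:
            n_excluded += 1
    return OCResult.from_counts(
        design=design,
        scenario_id=scenario_id,
        n=n,
        tau=model.tau,
        gamma=model.carryover,
        p_representative=model.p_representative,
        n_reps=B,
        n_rejected=n_rejected,
        n_excluded=n_excluded,
    )


def _check_grid(grid, name: str) -> None:
    grid = list(grid)
    if not grid:
        raise ValueError(f"{name} must be non-empty")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError(f"{name} must be strictly increasing")


def power_curve(
    model: SimulationModel,
    design: str,
    n_grid,
    B: int,
    seed,
    adjust_carryover: bool = False,
    alpha: float = 0.05,
    scenario_id: int | None = None,
) -> list[OCResult]:
    """Rejection rate as a function of sample size (independent draws per point)."""
    n_grid = [int(n) for n in n_grid]
    _check_grid(n_grid, "n_grid")
    children = _as_seedseq(seed).spawn(len(n_grid))
    return [
        run_oc(model, design, n, B, child, adjust_carryover, alpha, scenario_id)
        for n, child in zip(n_grid, children)
    ]


def tau_curve(
    model: SimulationModel,
    design: str,
    tau_grid,
    n: int,
    B: int,
    seed,
    adjust_carryover: bool = False,
    alpha: float = 0.05,
    scenario_id: int | None = None,
) -> list[OCResult]:
    """Rejection rate as a function of the true treatment effect at fixed ``n``.

    The ``tau = 0`` entry is the empirical type-I error.
    """
    tau_grid = [float(t) for t in tau_grid]
    _check_grid(tau_grid, "tau_grid")
    children = _as_seedseq(seed).spawn(len(tau_grid))
    return [
        run_oc(
            replace(model, tau=float(tau)),
            design,
            n,
            B,
            child,
            adjust_carryover,
            alpha,
            scenario_id,
        )
        for tau, child in zip(tau_grid, children)
    ]


def min_n_for_power(
    model: SimulationModel,
    design: str,
    target_power: float,
    n_grid,
    B: int,
    seed,
    adjust_carryover: bool = False,
    alpha: float = 0.05,
    scenario_id: int | None = None,
) -> int | None:
    """Smallest grid sample size whose estimated power reaches the target.

    Evaluates grid points in increasing order with the same per-point child
    seeds as :func:`power_curve`, stopping at the first qualifying point;
    returns None when no grid point qualifies.
    """
    if not 0.0 < target_power < 1.0:
        raise ValueError(f"target_power must be in (0, 1), got {target_power}")
    n_grid = [int(n) for n in n_grid]
    _check_grid(n_grid, "n_grid")
    children = _as_seedseq(seed).spawn(len(n_grid))
    for n, child in zip(n_grid, children):
        result = run_oc(model, design, n, B, child, adjust_carryover, alpha, scenario_id)
        if result.rejection_rate >= target_power:
            return int(n)
    return None


def selection_bias_oc(
    model: SimulationModel,
    design: str,
    n: int,
    p_grid,
    B: int,
    seed,
    mode: str = "type1",
    alpha: float = 0.05,
    scenario_id: int | None = None,
) -> list[OCResult]:
    """Operating characteristics under per-patient mixture sampling.

    In ``type1`` mode the target population has no effect (tau = 0) while
    the sub-population responds (tau_sub = 0.25): every rejection is a false
    conclusion about the target population, so the rejection rate is a
    type-I-error rate.  In ``power`` mode the roles are swapped
    (tau = 0.25, tau_sub = 0) and the rejection rate is the power for the
    target population.  One entry per sampling probability ``p``.
    """
    if mode == "type1":
        model = replace(model, tau=0.0, tau_sub=0.25)
    elif mode == "power":
        model = replace(model, tau=0.25, tau_sub=0.0)
    else:
        raise ValueError(f"mode must be 'type1' or 'power', got {mode!r}")
    p_grid = [float(p) for p in p_grid]
    if not p_grid:
        raise ValueError("p_grid must be non-empty")
    if any(not 0.0 <= p <= 1.0 for p in p_grid):
        raise ValueError("every p in p_grid must lie in [0, 1]")
    children = _as_seedseq(seed).spawn(len(p_grid))
    return [
        run_oc(
            replace(model, p_representative=p),
            design,
            n,
            B,
            child,
            False,
            alpha,
            scenario_id,
        )
        for p, child in zip(p_grid, children)
    ]


def compare_random_effects(
    model: SimulationModel, n: int, p: float, B: int, seed
) -> tuple[REComparison, REComparison]:
    """BLUP separation of sub-population vs target patients, N-of-1 vs crossover.

    For each replicate the shared cohort is analyzed under both designs with
    the intercept-plus-treatment mixed model, and the difference in mean
    predicted random intercept (sub-population minus representative
    patients) is recorded.  Replicates with an empty group, or whose fit
    fails, are skipped for the affected design.

    The caller configures the mixture through ``model.tau`` / ``model.tau_sub``;
    in the reference setting the target population has no effect
    (``tau = 0``) while the sub-population responds (``tau_sub = 0.25``), so
    a positive difference means the responders' random intercepts are
    predicted higher.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be strictly inside (0, 1), got {p}")
    model = replace(model, p_representative=p)
    diffs: dict[str, list[float]] = {"nof1": [], "crossover": []}
    for child in _as_seedseq(seed).spawn(B):
        rng = np.random.default_rng(child)
        cohort = simulate_cohort(model, n, rng)
        # per-patient population label from each patient's first record
        first = np.concatenate(([True], cohort.patient_id[1:] != cohort.patient_id[:-1]))
        labels = cohort.population[first]
        if not ((labels == REPRESENTATIVE).any() and (labels == SUBPOPULATION).any()):
            continue
        for design in ("nof1", "crossover"):
            data = extract_design(cohort, design, rng)
            try:
                fit = fit_random_intercept_ml(data, include_treatment=True)
            except FitError:
                continue
            blups = np.fromiter(
                (fit.blups[int(pid)] for pid in cohort.patient_id[first]), dtype=float
            )
            rep_mean = blups[labels == REPRESENTATIVE].mean()
            sub_mean = blups[labels == SUBPOPULATION].mean()
            diffs[design].append(float(sub_mean - rep_mean))
    return (
        REComparison("nof1", B, np.asarray(diffs["nof1"])),
        REComparison("crossover", B, np.asarray(diffs["crossover"])),
    )


# ---------------------------------------------------------------------------
# tabular round-trip

_OC_COLUMNS = [
    "design",
    "scenario_id",
    "n",
    "tau",
    "gamma",
    "p_representative",
    "n_reps",
    "n_rejected",
    "n_excluded",
    "rejection_rate",
    "mc_se",
]


def oc_results_to_frame(results: list[OCResult]) -> pd.DataFrame:
    """One tidy row per OCResult."""
    return pd.DataFrame([{c: getattr(r, c) for c in _OC_COLUMNS} for r in results])


def frame_to_oc_results(frame: pd.DataFrame) -> list[OCResult]:
    out = []
    for row in frame.itertuples(index=False):
        sid = row.scenario_id
        sid = None if pd.isna(sid) else int(sid)
        out.append(
            OCResult.from_counts(
                design=str(row.design),
                scenario_id=sid,
                n=int(row.n),
                tau=float(row.tau),
                gamma=float(row.gamma),
                p_representative=float(row.p_representative),
                n_reps=int(row.n_reps),
                n_rejected=int(row.n_rejected),
                n_excluded=int(row.n_excluded),
            )
        )
    return out
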