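"""Generative model and design extraction for aggregated N-of-1 trial simulations.

The generative model is a random-intercept linear model

    Y_ick = mu_i + tau * Z_ick + eps_ick,
    mu_i ~ Normal(mu, sigma_mu^2),  eps_ick ~ Normal(0, sigma_eps^2),

where patient ``i`` is observed over ``c`` treatment cycles, each cycle
containing two observation periods ("looks"): one under the new therapy
(``Z = 1``) and one under placebo (``Z = 0``), in randomized order.

A single simulated cohort supplies data for three designs so that design
comparisons are made on identical outcome draws:

* ``nof1``       -- every (cycle, look) record, 2c per patient;
* ``crossover``  -- the two cycle-1 records per patient;
* ``rct``        -- one cycle-1 record per patient, chosen uniformly
  (outcome and treatment assignment kept together).

Carryover is modeled as a fixed additive increment ``gamma`` applied to any
period whose chronological predecessor, within the design's own period
sequence, was a treated period.  Selection bias is modeled as a per-patient
mixture: with probability ``p_representative`` the patient comes from the
target population (effect ``tau``), otherwise from a sub-population with
effect ``tau_sub``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SCENARIOS",
    "DESIGNS",
    "SimulationModel",
    "TrialDataset",
    "simulate_cohort",
    "extract_design",
    "apply_carryover",
]

#: The four (sigma_mu, sigma_eps) variance scenarios studied: weak
#: heterogeneity / moderate error, homogeneity / moderate error, strong
#: heterogeneity / moderate error, strong heterogeneity / large error.
SCENARIOS: dict[int, tuple[float, float]] = {
    1: (0.1, 0.5),
    2: (0.0, 0.5),
    3: (0.5, 0.5),
    4: (0.5, 1.0),
}

DESIGNS = ("nof1", "crossover", "rct")

REPRESENTATIVE = 0
SUBPOPULATION = 1

_CSV_COLUMNS = [
    "patient_id",
    "cycle",
    "look",
    "treatment",
    "outcome",
    "prev_treated",
    "population",
]


@dataclass(frozen=True)
class SimulationModel:
    """All generative parameters for one simulation setting.

    Parameters
    ----------
    mu : float
        Grand mean of the outcome.  Operating characteristics are invariant
        to ``mu`` because the intercept is always estimated; default 0.
    tau : float
        Treatment effect for the target (representative) population.
    sigma_mu : float
        Between-patient SD of the random intercept; must be >= 0.
    sigma_eps : float
        Residual SD; must be > 0.
    n_cycles : int
        Number of treatment cycles ``c`` per patient (default 3).
    looks_per_cycle : int
        Observation periods per cycle; fixed at 2 (one per condition).
    carryover : float
        Additive carryover increment ``gamma`` (>= 0) applied by
        :func:`apply_carryover`.
    p_representative : float
        Probability that a patient is drawn from the target population.
    tau_sub : float
        Treatment effect in the non-representative sub-population.
    reorder_each_cycle : bool
        If True (default), the within-cycle condition order is re-randomized
        independently every cycle; if False, each patient keeps the order of
        their first cycle throughout.
    """

    mu: float = 0.0
    tau: float = 0.25
    sigma_mu: float = 0.1
    sigma_eps: float = 0.5
    n_cycles: int = 3
    looks_per_cycle: int = 2
    carryover: float = 0.0
    p_representative: float = 1.0
    tau_sub: float = 0.0
    reorder_each_cycle: bool = True

    def __post_init__(self) -> None:
        if self.sigma_mu < 0:
            raise ValueError(f"sigma_mu must be >= 0, got {self.sigma_mu}")
        if self.sigma_eps <= 0:
            raise ValueError(f"sigma_eps must be > 0, got {self.sigma_eps}")
        if self.n_cycles < 1:
            raise ValueError(f"n_cycles must be >= 1, got {self.n_cycles}")
        if self.looks_per_cycle != 2:
            raise ValueError("looks_per_cycle is fixed at 2 (one look per condition)")
        if self.carryover < 0:
            raise ValueError(f"carryover must be >= 0, got {self.carryover}")
        if not 0.0 <= self.p_representative <= 1.0:
            raise ValueError(
                f"p_representative must be in [0, 1], got {self.p_representative}"
            )

    @classmethod
    def scenario(cls, scenario_id: int, **overrides) -> "SimulationModel":
        """Build a model from one of the four named variance scenarios."""
        try:
            sigma_mu, sigma_eps = SCENARIOS[scenario_id]
        except KeyError:
            raise ValueError(
                f"unknown scenario {scenario_id!r}; valid ids are 1-4"
            ) from None
        overrides.setdefault("sigma_mu", sigma_mu)
        overrides.setdefault("sigma_eps", sigma_eps)
        return cls(**overrides)


@dataclass
class TrialDataset:
    """Long-format observation records for one simulated cohort under one design.

    Records are stored as parallel numpy arrays, chronologically ordered
    within patient (ascending cycle, then look).  ``prev_treated`` flags
    records whose immediately preceding period, in this design's own
    chronology, was a treated period; it is 0 for each patient's first
    period.
    """

    design: str
    patient_id: np.ndarray
    cycle: np.ndarray
    look: np.ndarray
    treatment: np.ndarray
    outcome: np.ndarray
    prev_treated: np.ndarray
    population: np.ndarray
    seed_info: str = ""

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}; expected one of {DESIGNS}")
        n = len(self.outcome)
        for name in ("patient_id", "cycle", "look", "treatment", "prev_treated", "population"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name!r} has inconsistent length")

    # -- basic introspection -------------------------------------------------

    @property
    def n_records(self) -> int:
        return len(self.outcome)

    @property
    def n_patients(self) -> int:
        return len(np.unique(self.patient_id))

    # -- serialization -------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format view with one row per observation period."""
        return pd.DataFrame(
            {
                "patient_id": self.patient_id,
                "cycle": self.cycle,
                "look": self.look,
                "treatment": self.treatment,
                "outcome": self.outcome,
                "prev_treated": self.prev_treated,
                "population": np.where(
                    self.population == REPRESENTATIVE, "representative", "subpopulation"
                ),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, design: str, seed_info: str = "") -> "TrialDataset":
        pop = np.where(
            frame["population"].to_numpy() == "representative",
            REPRESENTATIVE,
            SUBPOPULATION,
        ).astype(np.int8)
        return cls(
            design=design,
            patient_id=frame["patient_id"].to_numpy(dtype=np.int64),
            cycle=frame["cycle"].to_numpy(dtype=np.int64),
            look=frame["look"].to_numpy(dtype=np.int64),
            treatment=frame["treatment"].to_numpy(dtype=np.int8),
            outcome=frame["outcome"].to_numpy(dtype=np.float64),
            prev_treated=frame["prev_treated"].to_numpy(dtype=np.int8),
            population=pop,
            seed_info=seed_info,
        )

    @classmethod
    def from_csv(cls, path, design: str = "nof1") -> "TrialDataset":
        return cls.from_frame(pd.read_csv(path), design=design)


def _first_period_mask(patient_id: np.ndarray) -> np.ndarray:
    """True at each patient's first chronological record (input is patient-sorted)."""
    mask = np.empty(len(patient_id), dtype=bool)
    if len(mask):
        mask[0] = True
        mask[1:] = patient_id[1:] != patient_id[:-1]
    return mask

def compute_prev_treated(patient_id: np.ndarray, treatment: np.ndarray) -> np.ndarray:
    """Previous-period treatment indicator under the record ordering given.

    Records must be chronologically ordered within patient; the flag is 0 at
    each patient's first period and equals the preceding record's treatment
    value otherwise.
    """
    prev = np.empty(len(treatment), dtype=np.int8)
    if len(prev):
        prev[0] = 0
        prev[1:] = treatment[:-1]
        prev[_first_period_mask(patient_id)] = 0
    return prev


def simulate_cohort(
    model: SimulationModel, n: int, rng: np.random.Generator, seed_info: str = ""
) -> TrialDataset:
    """Simulate a full N-of-1 cohort of ``n`` patients (carryover not applied).

    Draws, in fixed stream order: per-patient population labels, random
    intercepts ``mu_i``, per-cycle condition orders, and residuals.  Patients
    from the target population receive treatment effect ``model.tau``,
    sub-population patients ``model.tau_sub``.
    """
    if n < 2:
        raise ValueError(f"need at least 2 patients, got n={n}")
    c = model.n_cycles

    representative = rng.random(n) < model.p_representative
    population = np.where(representative, REPRESENTATIVE, SUBPOPULATION).astype(np.int8)
    tau_i = np.where(representative, model.tau, model.tau_sub)

    mu_i = model.mu + model.sigma_mu * rng.standard_normal(n)

    if model.reorder_each_cycle:
        treat_first = rng.random((n, c)) < 0.5
    else:
        treat_first = np.broadcast_to((rng.random(n) < 0.5)[:, None], (n, c)).copy()

    # treatment[:, :, 0] is look 1, treatment[:, :, 1] is look 2
    treatment = np.empty((n, c, 2), dtype=np.int8)
    treatment[:, :, 0] = treat_first
    treatment[:, :, 1] = ~treat_first

    eps = model.sigma_eps * rng.standard_normal((n, c, 2))
    outcome = mu_i[:, None, None] + tau_i[:, None, None] * treatment + eps

    patient_id = np.repeat(np.arange(n, dtype=np.int64), 2 * c)
    cycle = np.tile(np.repeat(np.arange(1, c + 1, dtype=np.int64), 2), n)
    look = np.tile(np.array([1, 2] * c, dtype=np.int64), n)
    treatment_flat = treatment.reshape(-1)

    return TrialDataset(
        design="nof1",
        patient_id=patient_id,
        cycle=cycle,
        look=look,
        treatment=treatment_flat,
        outcome=outcome.reshape(-1),
        prev_treated=compute_prev_treated(patient_id, treatment_flat),
        population=np.repeat(population, 2 * c),
        seed_info=seed_info,
    )


def extract_design(
    cohort: TrialDataset, design: str, rng: np.random.Generator | None = None
) -> TrialDataset:
    """Derive a design-specific dataset from a full N-of-1 cohort.

    The same outcome draws underlie every design: ``crossover`` keeps both
    cycle-1 records per patient, ``rct`` keeps one cycle-1 record per patient
    chosen uniformly (requires ``rng``), and ``nof1`` is the identity.
    Outcomes are never re-sampled; ``prev_treated`` is recomputed within the
    extracted design's own chronology.
    """
    if cohort.design != "nof1":
        raise ValueError("design extraction starts from a full N-of-1 cohort")
    if design == "nof1":
        return cohort
    if design == "crossover":
        keep = cohort.cycle == 1
    elif design == "rct":
        if rng is None:
            raise ValueError("rct extraction requires an rng to pick one look per patient")
        n = cohort.n_patients
        chosen_look = rng.integers(1, 3, size=n)  # uniform over {1, 2}
        keep = (cohort.cycle == 1) & (cohort.look == chosen_look[cohort.patient_id])
    else:
        raise ValueError(f"unknown design {design!r}; expected one of {DESIGNS}")

    patient_id = cohort.patient_id[keep]
    treatment = cohort.treatment[keep]
    return TrialDataset(
        design=design,
        patient_id=patient_id,
        cycle=cohort.cycle[keep],
        look=cohort.look[keep],
        treatment=treatment,
        outcome=cohort.outcome[keep].copy(),
        prev_treated=compute_prev_treated(patient_id, treatment),
        population=cohort.population[keep],
        seed_info=cohort.seed_info,
    )


def apply_carryover(data: TrialDataset, gamma: float) -> TrialDataset:
    """Add the carryover increment ``gamma`` to every post-treatment period.

    A record receives a single ``+gamma`` when its chronological predecessor
    within this design's own period sequence was treated (carryover does not
    compound over consecutive treated periods).  For the N-of-1 design this
    acts both within and between cycles; for the crossover design only when
    placebo follows treatment; parallel RCT data (single period per patient)
    are returned unchanged.
    """
    if gamma < 0:
        raise ValueError(f"carryover increment must be >= 0, got {gamma}")
    prev = compute_prev_treated(data.patient_id, data.treatment)
    if data.design == "rct" or gamma == 0.0:
        return replace(data, prev_treated=prev)
    return replace(data, outcome=data.outcome + gamma * prev, prev_treated=prev)
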