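"""Synthetic trackway generator and parameter-recovery experiments.

The generator inverts the biometric models: individuals get an age, a
stature consistent with the foot-growth reference through the
foot-length/stature ratio (0.1541) with lognormal individual variation,
and a nine-variable foot template (measurement proportions relative to
maximum foot length, by default the mean proportion profile of the
packaged reference table).  Footprints are the template scaled by foot
length under multiplicative lognormal measurement noise — substrate
plasticity distorts positive lengths proportionally — with cells knocked
out at a missing-at-random rate, mimicking the missingness of the real
table.  Everything is driven by one master seed; per-replicate generators
are spawned from ``numpy.random.SeedSequence(seed).spawn``, so identical
seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .biometry import (
    GROWTH_REFERENCE,
    FOOT_STATURE_RATIO,
    GrowthReference,
    body_mass,
    profile_individuals,
    select_mass_models,
)
from .morphometry import group_morphotypes, minimum_individuals
from .records import PCA_VARIABLES, FootprintTable


@dataclass
class SyntheticIndividual:
    """Ground-truth individual for recovery experiments."""

    id: str
    true_age: float                 # years
    true_stature: float             # cm
    true_mass: float                # kg, under the matching mass model
    foot_length: float              # cm, = stature * ratio
    foot_template: np.ndarray       # nine proportions of max_FL
    sex: str                        # male | female


@dataclass
class TrackScenario:
    """Conditions of a simulated trackway assemblage."""

    individuals: list[SyntheticIndividual]
    footprints_per_individual: int = 5
    measurement_noise_cv: float = 0.02
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.measurement_noise_cv < 0:
            raise ValueError("noise CV must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing rate must lie in [0, 1)")


def _default_template() -> np.ndarray:
    """Mean proportion profile (nine variables / max_FL) of the reference table."""
    from .io import load_basura_fixtures

    t4 = load_basura_fixtures("table4").measurement_matrix()
    t3 = load_basura_fixtures("table3").data.set_index("footprint_id")["max_FL"]
    props = t4.div(t3.reindex(t4.index), axis=0)
    return props.mean(axis=0, skipna=True).to_numpy(float)


_TEMPLATE_CACHE: Optional[np.ndarray] = None


def default_foot_template() -> np.ndarray:
    global _TEMPLATE_CACHE
    if _TEMPLATE_CACHE is None:
        _TEMPLATE_CACHE = _default_template()
    return _TEMPLATE_CACHE.copy()


def generate_population(
    n: int,
    age_range: tuple[float, float] = (2.0, 30.0),
    seed: int = 0,
    *,
    ages: Optional[Sequence[float]] = None,
    stature_cv: float = 0.04,
    ratio: float = FOOT_STATURE_RATIO,
    growth: GrowthReference = GROWTH_REFERENCE,
) -> list[SyntheticIndividual]:
    """Draw ``n`` individuals of mixed age with stature-linked foot length.

    Ages are uniform over ``age_range`` (or given explicitly); the expected
    foot length comes from the growth reference and is perturbed by
    lognormal individual variation of coefficient ``stature_cv`` (0.04 by
    default, within the printed anchor SD bands); stature is foot length
    over the 0.1541 ratio.  Deterministic under ``seed``.
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    lo, hi = age_range
    if not (0 < lo <= hi):
        raise ValueError(f"invalid age range {age_range}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if ages is None:
        ages = rng.uniform(lo, hi, size=n)
    elif len(ages) != n:
        raise ValueError("ages, when given, must have length n")
    sexes = rng.choice(["male", "female"], size=n)
    pop = []
    template = default_foot_template()
    for i, age in enumerate(ages):
        fl = growth.foot_length_at(float(age))
        if stature_cv > 0:
            sigma = np.sqrt(np.log1p(stature_cv**2))
            fl *= np.exp(rng.normal(0.0, sigma) - 0.5 * sigma**2)
        stature = fl / ratio
        model = select_mass_models(stature)[0]
        pop.append(
            SyntheticIndividual(
                id=f"I{i + 1:02d}",
                true_age=float(age),
                true_stature=float(stature),
                true_mass=float(body_mass(fl, model)),
                foot_length=float(fl),
                foot_template=template,
                sex=str(sexes[i]),
            )
        )
    return pop


def simulate_footprints(
    pop: Sequence[SyntheticIndividual], scenario: TrackScenario
) -> FootprintTable:
    """Simulate a measurement table structurally identical to the real one.

    Each footprint's nine variables are the individual's template times its
    foot length times per-cell multiplicative lognormal noise (CV =
    ``measurement_noise_cv``); ``max_FL`` gets the same noise model.  Cells
    of the nine variables go missing independently with probability
    ``missing_rate`` (``max_FL`` is kept, as in the real table).
    """
    rng = np.random.default_rng(np.random.SeedSequence(scenario.seed))
    cv = scenario.measurement_noise_cv
    sigma = np.sqrt(np.log1p(cv**2)) if cv > 0 else 0.0

    def noise(size):
        if sigma == 0.0:
            return np.ones(size)
        return np.exp(rng.normal(0.0, sigma, size=size) - 0.5 * sigma**2)

    rows = []
    for ind in pop:
        base = ind.foot_template * ind.foot_length
        for j in range(scenario.footprints_per_individual):
            vals = base * noise(len(base))
            if scenario.missing_rate > 0:
                drop = rng.random(len(vals)) < scenario.missing_rate
                vals = np.where(drop, np.nan, vals)
            row = {"footprint_id": f"{ind.id}_F{j + 1}"}
            row.update(dict(zip(PCA_VARIABLES, vals)))
            row["max_FL"] = ind.foot_length * float(noise(1)[0])
            rows.append(row)
    df = pd.DataFrame(rows, columns=["footprint_id", *PCA_VARIABLES, "max_FL"])
    return FootprintTable(df)


@dataclass
class RecoveryReport:
    """Pipeline performance over replicated synthetic assemblages."""

    n_reps: int
    true_n: int
    mni_accuracy: float                 # fraction of reps with exact MNI
    stature_bias: float                 # cm, mean(estimate - truth)
    stature_rmse: float                 # cm
    mass_rmse: dict[str, float] = field(default_factory=dict)  # kg per model
    age_confusion: pd.DataFrame = None  # true class x estimated class counts
    mni_counts: dict[int, int] = field(default_factory=dict)


def recovery_experiment(
    scenario: TrackScenario,
    pipeline_config: Optional[dict] = None,
    n_reps: int = 20,
    seed: int = 0,
) -> RecoveryReport:
    """Run the full pipeline on replicated simulations and score recovery.

    Each replicate regenerates footprints from the scenario's individuals
    under a fresh child seed, clusters them into morphotypes, profiles the
    groups, and compares: MNI against the true number of individuals, and
    (for replicates with the correct MNI) group stature/mass against truth
    after size-ordered matching.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    from .biometry import age_class  # local to avoid cycle at import time

    pop = sorted(scenario.individuals, key=lambda d: d.foot_length)
    true_n = len(pop)
    streams = np.random.SeedSequence(seed).spawn(n_reps)

    hits = 0
    st_err, mass_err, mni_counts = [], {"a": [], "b": []}, {}
    age_pairs = []
    for child in streams:
        rep_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        rep = TrackScenario(
            individuals=list(scenario.individuals),
            footprints_per_individual=scenario.footprints_per_individual,
            measurement_noise_cv=scenario.measurement_noise_cv,
            missing_rate=scenario.missing_rate,
            seed=rep_seed,
        )
        table = simulate_footprints(rep.individuals, rep)
        assignment = group_morphotypes(table, config=pipeline_config)
        mni = minimum_individuals(assignment)
        mni_counts[mni] = mni_counts.get(mni, 0) + 1
        if mni != true_n:
            continue
        hits += 1
        est = profile_individuals(table, assignment, config=pipeline_config)
        est = sorted(est, key=lambda e: e.fl_mean)
        for ind, e in zip(pop, est):
            st_err.append(e.stature_mean - ind.true_stature)
            model = select_mass_models(ind.true_stature)[0]
            if model in e.mass_by_model:
                mass_err[model].append(e.mass_by_model[model][0] - ind.true_mass)
            truth_cls = age_class(
                ind.foot_length,
                adult_morphology=ind.true_stature >= 147,
            ).age_class
            age_pairs.append((truth_cls, e.age.age_class))

    if st_err:
        bias = float(np.mean(st_err))
        rmse = float(np.sqrt(np.mean(np.square(st_err))))
    else:
        bias = rmse = float("nan")
    mass_rmse = {
        m: float(np.sqrt(np.mean(np.square(v)))) for m, v in mass_err.items() if v
    }
    if age_pairs:
        conf = (
            pd.DataFrame(age_pairs, columns=["true", "estimated"])
            .value_counts()
            .unstack(fill_value=0)
        )
    else:
        conf = pd.DataFrame()
    return RecoveryReport(
        n_reps=n_reps,
        true_n=true_n,
        mni_accuracy=hits / n_reps,
        stature_bias=bias,
        stature_rmse=rmse,
        mass_rmse=mass_rmse,
        age_confusion=conf,
        mni_counts=dict(sorted(mni_counts.items())),
    )
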