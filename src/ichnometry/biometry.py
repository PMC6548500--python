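"""Biological inference from footprint measurements.

Closed-form anthropometric relations link the maximum foot length (FL, cm)
of a footprint to the producer's stature, body mass and age class:

* stature  S = FL / R with the foot-length/stature ratio R = 0.1541
  (calibrated on terminal Upper Palaeolithic adult skeletons), checked for
  the largest producer against the tibial regressions
  S = 101.85 + 1.81·PCTL ± 3.73 (male) and S = 77.86 + 2.36·PCTL ± 2.94
  (female), PCTL = percutaneous tibial length in cm;
* body mass, three models — (a) child exponential m = 2.2897·e^(0.126·FL),
  (b) adult linear m = 4.71 + 1.82·FL (calibrated on statures 154–185 cm),
  (c) child/adolescent linear m = −71.142 + 5.259·FL (calibrated on a
  cohort averaging 147.44 cm; positive only for FL > 13.53);
* age, by linear interpolation between growth anchors (1 yr → 13.07 cm,
  13 yr → 24.4 cm) with arch-angle development bands as a consistency
  note (21°→43° for boys, 26°→47° for girls over ages ~3–4 to 9–11);
* sex, a deliberately transparent and low-confidence rule table — the
  approach is speculative and every call carries its rationale.

All report-facing numbers are rounded half-up to 2 decimals; group
summaries are mean ± sample SD (n−1) over unrounded per-footprint values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .morphometry import MorphotypeAssignment, foot_index
from .records import FootprintTable
from .utils import round_half_up

FOOT_STATURE_RATIO = 0.1541

AGE_CLASSES = ("<3", "5–6", "8–11", ">14 - adult")


@dataclass(frozen=True)
class StatureModel:
    """Foot-length ratio and tibial regressions for stature (cm)."""

    foot_ratio: float = FOOT_STATURE_RATIO
    tibia_male: tuple[float, float, float] = (101.85, 1.81, 3.73)    # a, b, ±band
    tibia_female: tuple[float, float, float] = (77.86, 2.36, 2.94)


@dataclass(frozen=True)
class MassModel:
    """Coefficients of the three body-mass models (kg from FL in cm)."""

    model_a: tuple[float, float] = (2.2897, 0.126)      # m = c * exp(k FL)
    model_b: tuple[float, float] = (4.71, 1.82)         # m = a + b FL
    model_c: tuple[float, float] = (-71.142, 5.259)     # m = a + b FL
    #: group mean stature at/above which the adult models apply
    adult_stature_min: float = 147.0
    #: model c only for adult-class groups near its calibration height
    model_c_max_stature: float = 152.0


@dataclass(frozen=True)
class GrowthReference:
    """Foot-length growth anchors and arch-angle development bands."""

    #: (age yr, foot length cm, SD cm)
    anchors: tuple[tuple[float, float, float], ...] = (
        (1.0, 13.07, 1.59),
        (13.0, 24.4, 2.96),
    )
    #: arch angle from ~3-4 yr to ~9-11 yr
    arch_band_male: tuple[float, float] = (21.0, 43.0)
    arch_band_female: tuple[float, float] = (26.0, 47.0)
    arch_band_ages: tuple[float, float] = (3.5, 10.0)

    def foot_length_at(self, age: float) -> float:
        """Expected foot length at an age (linear between/through anchors)."""
        (a0, f0, _), (a1, f1, _) = self.anchors
        slope = (f1 - f0) / (a1 - a0)
        if age <= a1:
            return f0 + slope * (age - a0)
        # juvenile growth decelerates after the last anchor: half slope to a
        # plateau at age 16 (adult foot size)
        adult_age = 16.0
        return f1 + 0.5 * slope * (min(age, adult_age) - a1)

    def age_at(self, fl: float) -> tuple[float, bool]:
        """Interpolated point age for a foot length; flags clamping."""
        (a0, f0, _), (a1, f1, _) = self.anchors
        slope = (f1 - f0) / (a1 - a0)
        if fl < f0:
            return a0, True
        if fl <= f1:
            return a0 + (fl - f0) / slope, False
        adult_fl = self.foot_length_at(16.0)
        if fl >= adult_fl:
            return 16.0, True
        return a1 + (fl - f1) / (0.5 * slope), False


GROWTH_REFERENCE = GrowthReference()


# ---------------------------------------------------------------------------
# elementary estimators
# ---------------------------------------------------------------------------

def stature_from_foot_length(max_FL: float, R: float = FOOT_STATURE_RATIO) -> float:
    """Stature (cm) as foot length over the foot-length/stature ratio."""
    if not max_FL > 0:
        raise ValueError(f"foot length must be positive, got {max_FL}")
    return max_FL / R


def stature_from_tibia(
    PCTL: float, sex: str, model: StatureModel = StatureModel()
) -> tuple[float, float]:
    """Stature (cm) ± band from percutaneous tibial length, by sex."""
    if not PCTL > 0:
        raise ValueError(f"tibial length must be positive, got {PCTL}")
    try:
        a, b, band = {"male": model.tibia_male, "female": model.tibia_female}[sex]
    except KeyError:
        raise ValueError(f"unknown sex {sex!r}; expected 'male' or 'female'") from None
    return a + b * PCTL, band


def body_mass(max_FL: float, model: str, coeffs: MassModel = MassModel()) -> float:
    """Body mass (kg) from maximum foot length under one closed-form model."""
    if not max_FL > 0:
        raise ValueError(f"foot length must be positive, got {max_FL}")
    if model == "a":
        c, k = coeffs.model_a
        return c * math.exp(k * max_FL)
    if model == "b":
        a, b = coeffs.model_b
        return a + b * max_FL
    if model == "c":
        a, b = coeffs.model_c
        m = a + b * max_FL
        if m <= 0:
            raise ValueError(
                f"model c yields non-positive mass at FL={max_FL} "
                f"(admissible only above {-a / b:.2f} cm)"
            )
        return m
    raise ValueError(f"unknown mass model {model!r}; expected 'a', 'b' or 'c'")


def select_mass_models(
    stature: float,
    morphotype_size_class: Optional[str] = None,
    coeffs: MassModel = MassModel(),
) -> tuple[str, ...]:
    """Which mass models apply for a group of a given (mean) stature.

    Child-class groups get the exponential child model (a); adult-class
    groups the adult linear model (b), plus the child/adolescent linear
    model (c) when the group stature is near that model's calibration
    height (≤ ~152 cm).
    """
    if not stature > 0:
        raise ValueError(f"stature must be positive, got {stature}")
    if morphotype_size_class is None:
        morphotype_size_class = (
            "adult" if stature >= coeffs.adult_stature_min else "child"
        )
    if morphotype_size_class in ("child", "adolescent"):
        return ("a",)
    models: tuple[str, ...] = ("b",)
    if stature <= coeffs.model_c_max_stature:
        models += ("c",)
    return models


@dataclass
class AgeEstimate:
    point_age: float
    age_class: str
    clamped: bool = False
    arch_note: Optional[str] = None


def age_class(
    max_FL: float,
    Aa: Optional[float] = None,
    *,
    adult_morphology: bool = False,
    growth: GrowthReference = GROWTH_REFERENCE,
) -> AgeEstimate:
    """Age class (and interpolated point age) from foot length.

    The point age is a monotone linear interpolation between the growth
    anchors; the class is the vocabulary bin containing it (edges 4.5, 7
    and 12 years bracket the published class assignments).  Adult-class
    morphology forces the adult bin.  When the arch angle is present it is
    compared against the juvenile development bands as a consistency note.
    """
    if not max_FL > 0:
        raise ValueError(f"foot length must be positive, got {max_FL}")
    age, clamped = growth.age_at(max_FL)
    if adult_morphology or age >= 12.0:
        cls = ">14 - adult"
    elif age < 4.5:
        cls = "<3"
    elif age < 7.0:
        cls = "5–6"
    else:
        cls = "8–11"
    note = None
    if Aa is not None and not adult_morphology:
        lo = min(growth.arch_band_male[0], growth.arch_band_female[0])
        hi = max(growth.arch_band_male[1], growth.arch_band_female[1])
        if lo <= Aa <= hi:
            note = (
                f"arch angle {Aa:g}° lies within the juvenile development "
                f"band ({lo:g}°–{hi:g}°), consistent with age class {cls}"
            )
        else:
            note = (
                f"arch angle {Aa:g}° falls outside the juvenile development "
                f"band ({lo:g}°–{hi:g}°)"
            )
    return AgeEstimate(point_age=age, age_class=cls, clamped=clamped, arch_note=note)


@dataclass
class SexCall:
    call: str            # probable_male | probable_female | indeterminate
    rationale: str
    low_confidence: bool = True


def infer_sex(group_stats: dict, rules: Optional[dict] = None) -> SexCall:
    """Sex call for a morphotype group from its summary statistics.

    ``group_stats`` keys: ``size_class`` ('child'/'adolescent'/'adult'),
    ``robust`` (stout-morphology flag, e.g. mean foot index at or above the
    configured threshold), ``is_largest``, and optionally ``mean_FI`` and
    ``mean_Aa``.  Default rule table: the largest adult-class group with
    robust morphology → probable_male; optionally (``gracile_adult_female``)
    a gracile adult group → probable_female; everything else indeterminate.
    Foot-based sexing is speculative, so every call is flagged low
    confidence and carries its rationale.
    """
    if group_stats.get("n", 1) < 1:
        raise ValueError("empty group")
    rules = rules or {}
    size_class = group_stats.get("size_class")
    robust = bool(group_stats.get("robust", False))
    largest = bool(group_stats.get("is_largest", False))
    fi = group_stats.get("mean_FI")
    aa = group_stats.get("mean_Aa")
    detail = ", ".join(
        s for s in (
            f"mean FI {fi:.2f}" if fi is not None else None,
            f"mean arch angle {aa:.1f}°" if aa is not None and not (
                isinstance(aa, float) and math.isnan(aa)) else None,
        ) if s
    )
    if size_class == "adult" and robust and largest:
        return SexCall(
            "probable_male",
            "largest adult-class group with wide, stout footprint morphology"
            + (f" ({detail})" if detail else "")
            + "; foot-based sexing is speculative",
        )
    if (
        rules.get("gracile_adult_female", False)
        and size_class == "adult"
        and not robust
    ):
        return SexCall(
            "probable_female",
            "adult-class group with gracile footprint morphology"
            + (f" ({detail})" if detail else "")
            + "; foot-based sexing is speculative",
        )
    return SexCall(
        "indeterminate",
        "no reliable sex signal in footprint morphology"
        + (f" ({detail})" if detail else ""),
    )


def summarize_group(values: Sequence[float]) -> tuple[float, Optional[float]]:
    """Arithmetic mean and sample SD (n−1); SD is None for a single value."""
    vals = [float(v) for v in values]
    if len(vals) == 0:
        raise ValueError("cannot summarize an empty value list")
    mean = float(np.mean(vals))
    if len(vals) == 1:
        return mean, None
    return mean, float(np.std(vals, ddof=1))


# ---------------------------------------------------------------------------
# per-individual profiles
# ---------------------------------------------------------------------------

@dataclass
class BiometricEstimate:
    """Per-individual (morphotype) biometric profile with uncertainty."""

    label: int
    footprint_ids: list[str]
    n_footprints: int
    fl_mean: float
    fl_sd: Optional[float]
    fi_mean: Optional[float]
    fi_sd: Optional[float]
    stature_mean: float
    stature_sd: Optional[float]
    mass_models: tuple[str, ...]
    mass_by_model: dict[str, tuple[float, Optional[float]]]
    age: AgeEstimate = None
    sex: SexCall = None
    per_footprint: pd.DataFrame = None


def profile_individuals(
    T: FootprintTable,
    a: MorphotypeAssignment,
    models: Optional[dict] = None,
    config: Optional[dict] = None,
) -> list[BiometricEstimate]:
    """Stature, mass, age and sex per morphotype group.

    Per-footprint estimates are computed first from each footprint's
    maximum foot length, then summarized as mean ± sample SD (matching the
    published order of operations).  Footprints without a foot length are
    excluded from summaries; if the table carries an ``in_summary`` flag it
    selects the summarizing subset, otherwise all measurable group members
    are used.  Mass-model routing is decided at group level from the mean
    stature of the summarizing subset.
    """
    cfg = config or {}
    models = models or {}
    stature_model: StatureModel = models.get("stature", StatureModel())
    mass_coeffs: MassModel = models.get("mass", MassModel())
    growth: GrowthReference = models.get("growth", GROWTH_REFERENCE)
    ratio = float(cfg.get("ratio", stature_model.foot_ratio))
    fi_robust = float(cfg.get("fi_robust_threshold", 0.40))
    sex_rules = {
        "gracile_adult_female": bool(cfg.get("gracile_adult_female", False))
    }

    df = T.data.set_index("footprint_id")
    unassigned = [i for i in df.index if str(i) not in a.labels]
    measurable = [i for i in df.index if not pd.isna(df.loc[i].get("max_FL"))]
    missing = [i for i in measurable if str(i) in unassigned]
    if missing:
        raise ValueError(f"footprints not assigned to any group: {missing}")

    groups = sorted(set(a.labels.values()))
    # group mean FL (for 'largest group' flag), on summarizing subsets
    def subset_ids(g: int) -> list[str]:
        ids = [i for i in a.members(g) if i in df.index]
        ids = [i for i in ids if not pd.isna(df.loc[i].get("max_FL"))]
        if "in_summary" in df.columns:
            flagged = [i for i in ids if float(df.loc[i, "in_summary"] or 0) > 0]
            if flagged:
                ids = flagged
        return ids

    fl_means = {}
    for g in groups:
        ids = subset_ids(g)
        if ids:
            fl_means[g] = float(np.mean([df.loc[i, "max_FL"] for i in ids]))
    largest_group = max(fl_means, key=fl_means.get) if fl_means else None

    estimates: list[BiometricEstimate] = []
    for g in groups:
        ids = subset_ids(g)
        if not ids:
            continue
        fl = np.array([float(df.loc[i, "max_FL"]) for i in ids])
        statures = fl / ratio
        fl_mean, fl_sd = summarize_group(fl)
        st_mean, st_sd = summarize_group(statures)

        chosen = select_mass_models(st_mean, coeffs=mass_coeffs)
        mass_by_model: dict[str, tuple[float, Optional[float]]] = {}
        per_rows = {"footprint_id": ids, "max_FL": fl, "stature": statures}
        for m in chosen:
            mvals = np.array([body_mass(v, m, mass_coeffs) for v in fl])
            mass_by_model[m] = summarize_group(mvals)
            per_rows[f"mass_{m}"] = mvals

        fis = None
        if "max_FW" in df.columns:
            fw = [df.loc[i, "max_FW"] for i in ids]
            pairs = [(w, l) for w, l in zip(fw, fl) if not pd.isna(w)]
            if pairs:
                fis = [foot_index(w, l) for w, l in pairs]
        fi_mean, fi_sd = summarize_group(fis) if fis else (None, None)

        aa_vals = None
        if "Aa" in df.columns:
            aa_vals = [df.loc[i, "Aa"] for i in ids if not pd.isna(df.loc[i, "Aa"])]
        mean_aa = float(np.mean(aa_vals)) if aa_vals else None

        adult = "b" in chosen
        age = age_class(
            fl_mean, Aa=mean_aa, adult_morphology=adult, growth=growth
        )
        sex = infer_sex(
            {
                "n": len(ids),
                "size_class": "adult" if adult else "child",
                "robust": fi_mean is not None and fi_mean >= fi_robust,
                "is_largest": g == largest_group,
                "mean_FI": fi_mean,
                "mean_Aa": mean_aa,
            },
            rules=sex_rules,
        )
        estimates.append(
            BiometricEstimate(
                label=g,
                footprint_ids=list(ids),
                n_footprints=len(ids),
                fl_mean=fl_mean,
                fl_sd=fl_sd,
                fi_mean=fi_mean,
                fi_sd=fi_sd,
                stature_mean=st_mean,
                stature_sd=st_sd,
                mass_models=chosen,
                mass_by_model=mass_by_model,
                age=age,
                sex=sex,
                per_footprint=pd.DataFrame(per_rows),
            )
        )
    if not estimates:
        raise ValueError("no measurable footprints to profile")
    return estimates
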