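"""Seeded virtual-trial cohort generator.

Builds diseased synthetic coronary trees, produces an "invasive" FFR per
vessel from a reference hemodynamic model with per-vessel microvascular
variability plus measurement noise, simulates a CTA stenosis reading, and
assembles the per-vessel trial table.

The generator targets the trial's stratum marginals directly: each
vessel's FFR stratum (below gray zone / gray zone / non-ischemic) is drawn
from the configured multinomial, and the stenosis degree realizing that
measured FFR is found by inverting the monotone degree -> FFR map of the
reference model.  Degrees always stay inside the CTA inclusion window
[30, 90]% in vessels >= 2.0 mm; vessels whose geometry cannot reach the
drawn stratum are redrawn, and a configuration for which this keeps
failing raises a diagnostic error.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import InfeasibleCohortError, ValidationError
from .geometry import Lesion, VesselTree, apply_lesions, make_segment, plaque_burden
from .hemodynamics import BloodModel, BoundaryParams, ct_ffr

#: columns of the per-vessel trial table, in output order
COHORT_COLUMNS = [
    "vessel_id",
    "vessel_label",
    "ct_ffr",
    "measured_ffr",
    "cta_percent_stenosis",
    "cta_ge_50",
    "cta_ge_70",
    "true_degree",
    "lesion_length",
    "plaque_volume",
    "calcified_volume",
    "noncalcified_volume",
    "plaque_burden",
    "lumen_area",
    "lumen_diameter",
    "calcium_score",
]


@dataclass
class CohortConfig:
    """Study conditions of the synthetic trial.

    Stratum targets mirror the trial's per-vessel marginals: 46.2%
    ischemic (FFR < 0.80) of which 13.7% points sit in the gray zone
    [0.76, 0.80).  Lesion-length and calcified-fraction medians are set
    per stratum so plaque covariates rank as in the trial's burden tables
    (gray-zone lesions longer and more calcified than non-ischemic ones).
    """

    n_vessels: int = 366
    vessel_label_mix: dict = field(
        default_factory=lambda: {"LAD": 0.55, "LCX": 0.22, "RCA": 0.23}
    )
    degree_range: tuple[float, float] = (30.0, 90.0)
    min_vessel_diameter: float = 2.0
    ffr_noise_sd: float = 0.02
    vessel_effect_sd: float = 0.15
    cta_reader_sd: float = 8.0
    reference_theta: BoundaryParams = field(default_factory=BoundaryParams)
    target_ischemic_fraction: float = 169.0 / 366.0
    target_gray_fraction: float = 50.0 / 366.0
    measurement_offset: float = 25.0
    #: per-stratum median lesion length (mm): below gray / gray / non-ischemic
    lesion_length_medians: dict = field(
        default_factory=lambda: {"low": 22.3, "gray": 21.3, "high": 17.6}
    )
    lesion_length_sigma: float = 0.5
    #: per-stratum median calcified fraction of plaque volume
    calcified_fraction_medians: dict = field(
        default_factory=lambda: {"low": 0.08, "gray": 0.135, "high": 0.087}
    )
    calcified_fraction_sigma: float = 0.6
    min_measured_ffr: float = 0.30
    max_attempts: int = 60
    seed: int = 0

    def __post_init__(self):
        if self.n_vessels <= 0:
            raise ValidationError("n_vessels must be positive")
        total = sum(self.vessel_label_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError("vessel_label_mix proportions must sum to 1")
        if set(self.vessel_label_mix) - {"LAD", "LCX", "RCA"}:
            raise ValidationError("vessel labels must be LAD/LCX/RCA")
        lo, hi = self.degree_range
        if not (30.0 <= lo < hi <= 90.0):
            raise ValidationError("degree_range must be within [30, 90]")
        for name in ("ffr_noise_sd", "vessel_effect_sd", "cta_reader_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not (0.0 <= self.target_gray_fraction <= self.target_ischemic_fraction <= 1.0):
            raise ValidationError(
                "need 0 <= gray fraction <= ischemic fraction <= 1 "
                "(the gray zone is a subset of the ischemic class)"
            )

    def stratum_probabilities(self) -> dict[str, float]:
        low = self.target_ischemic_fraction - self.target_gray_fraction
        return {
            "low": low,
            "gray": self.target_gray_fraction,
            "high": 1.0 - self.target_ischemic_fraction,
        }


#: stratum FFR intervals, half-open on the right; the gray zone is part of
#: the ischemic class (FFR < 0.80)
STRATUM_INTERVALS = {
    "low": (None, 0.76),
    "gray": (0.76, 0.80),
    "high": (0.80, 0.995),
}

_LABEL_DIAMETER_MEAN = {"LAD": 3.3, "LCX": 2.9, "RCA": 3.4}


def cta_reading(
    true_degree: float, reader_sd: float, rng: np.random.Generator
) -> tuple[float, bool, bool]:
    """Noisy CTA percent-stenosis reading, truncated to [0, 100).

    Returns (reading, >=50% flag, >=70% flag).
    """
    if not (0.0 <= true_degree < 100.0):
        raise ValidationError("true degree must lie in [0, 100)")
    reading = true_degree + (rng.normal(0.0, reader_sd) if reader_sd > 0 else 0.0)
    reading = float(min(max(reading, 0.0), 100.0 - 1e-9))
    return reading, reading >= 50.0, reading >= 70.0


def invasive_ffr_oracle(
    tree: VesselTree,
    lesion: Lesion,
    reference_theta: BoundaryParams,
    vessel_effect_sd: float,
    noise_sd: float,
    rng: np.random.Generator,
    *,
    blood: BloodModel | None = None,
    offset: float = 25.0,
) -> float:
    """Emulated invasive FFR measurement.

    Reference-model FFR with the vessel's microvascular resistance
    perturbed log-normally (SD ``vessel_effect_sd`` on the log scale) plus
    additive measurement noise, truncated to (0, 1].
    """
    factor = math.exp(rng.normal(0.0, vessel_effect_sd)) if vessel_effect_sd > 0 else 1.0
    value = ct_ffr(
        tree, lesion, reference_theta, blood, offset=offset, outlet_factor=factor
    )
    if noise_sd > 0:
        value += rng.normal(0.0, noise_sd)
    return float(min(max(value, 1e-6), 1.0))


def _draw_vessel_geometry(
    rng: np.random.Generator, label: str, cfg: CohortConfig
) -> tuple[VesselTree, float, float]:
    """One healthy 3-segment tree (proximal trunk + distal continuation +
    side branch) with label-dependent calibre; returns (tree, lesion start
    window, trunk length)."""
    mean_d = _LABEL_DIAMETER_MEAN[label]
    d0 = float(np.clip(rng.normal(mean_d, 0.35),
                       max(2.3, cfg.min_vessel_diameter + 0.3), 4.5))
    trunk_len = float(rng.uniform(32.0, 50.0))
    dist_len = float(rng.uniform(25.0, 40.0))
    side_len = float(rng.uniform(15.0, 30.0))
    trunk = make_segment(trunk_len, d0, 0.92 * d0, segment_id="prox", is_outlet=False)
    dist = make_segment(
        dist_len, 0.88 * d0, 0.70 * d0, segment_id="dist", parent_id="prox",
        is_outlet=True,
    )
    side = make_segment(
        side_len, 0.68 * d0, 0.58 * d0, segment_id="side", parent_id="prox",
        is_outlet=True,
    )
    tree = VesselTree.from_segments([trunk, dist, side], label)
    return tree, d0, trunk_len


def _model_ffr(healthy, lesion_site, degree, cfg, applied=None, factor=1.0) -> float:
    from .hemodynamics import compile_network, compile_probe, fast_ct_ffr

    start, length = lesion_site
    lesion = Lesion("prox", start, length, degree)
    tree = apply_lesions(healthy, [lesion])
    net = compile_network(tree)
    probe = compile_probe(net, lesion, cfg.measurement_offset)
    theta = applied if applied is not None else cfg.reference_theta
    return fast_ct_ffr(net, probe, theta, outlet_factor=factor)


def generate_cohort(
    config: CohortConfig,
    applied_theta: BoundaryParams | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict[str, tuple[VesselTree, Lesion]]]:
    """Generate the per-vessel trial table and the underlying trees.

    ``applied_theta`` is the frozen parameter set used for the CT-FFR
    column (defaults to the reference parameters); measured FFR always
    comes from the reference model with per-vessel microvascular
    variability and measurement noise.  Reproducible for a fixed seed.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    labels = sorted(config.vessel_label_mix)
    label_p = np.array([config.vessel_label_mix[k] for k in labels])
    strata = ["low", "gray", "high"]
    strat_p = config.stratum_probabilities()
    p = np.array([strat_p[s] for s in strata])
    deg_lo, deg_hi = config.degree_range

    rows = []
    trees: dict[str, tuple[VesselTree, Lesion]] = {}
    for i in range(config.n_vessels):
        vessel_id = f"V{i:04d}"
        label = labels[int(rng.choice(len(labels), p=label_p))]
        stratum = strata[int(rng.choice(3, p=p))]
        placed = False
        for _attempt in range(config.max_attempts):
            healthy, d0, trunk_len = _draw_vessel_geometry(rng, label, cfg=config)
            med = config.lesion_length_medians[stratum]
            length = float(
                np.exp(rng.normal(np.log(med), config.lesion_length_sigma))
            )
            length = float(np.clip(length, 5.0, 0.8 * trunk_len))
            start = float(rng.uniform(2.0, trunk_len - length - 2.0))
            site = (start, length)
            factor = (
                math.exp(rng.normal(0.0, config.vessel_effect_sd))
                if config.vessel_effect_sd > 0
                else 1.0
            )
            noise = rng.normal(0.0, config.ffr_noise_sd) if config.ffr_noise_sd > 0 else 0.0
            f_hi = _model_ffr(healthy, site, deg_lo, config, factor=factor)
            f_lo = _model_ffr(healthy, site, deg_hi, config, factor=factor)
            lo_s, hi_s = STRATUM_INTERVALS[stratum]
            lo_s = config.min_measured_ffr if lo_s is None else lo_s
            lo_u = max(lo_s, f_lo + noise + 1e-6)
            hi_u = min(hi_s, f_hi + noise - 1e-6)
            if hi_u <= lo_u:
                continue  # this geometry cannot reach the drawn stratum
            u = float(rng.uniform(lo_u, hi_u))  # measured FFR, exact stratum hit
            target = u - noise  # noiseless reference-model value to realize

            def gap(deg):
                return _model_ffr(healthy, site, deg, config, factor=factor) - target

            degree = float(brentq(gap, deg_lo, deg_hi, xtol=1e-4))
            placed = True
            break
        if not placed:
            raise InfeasibleCohortError(
                f"vessel {vessel_id}: could not realize stratum {stratum!r} within "
                f"degree range {config.degree_range} after {config.max_attempts} "
                "attempts; the configuration is infeasible"
            )

        lesion = Lesion("prox", start, length, degree)
        stenosed = apply_lesions(healthy, [lesion])
        metrics = plaque_burden(stenosed.segments["prox"], lesion)
        calc_med = config.calcified_fraction_medians[stratum]
        calc_frac = float(
            np.clip(
                np.exp(rng.normal(np.log(calc_med), config.calcified_fraction_sigma)),
                0.0,
                0.95,
            )
        )
        calcified = calc_frac * metrics.plaque_volume_mm3
        noncalcified = metrics.plaque_volume_mm3 - calcified
        calcium_score = calcified * float(np.exp(rng.normal(np.log(1.5), 0.4)))
        lesion = replace(
            lesion,
            calcified_volume=calcified,
            noncalcified_volume=noncalcified,
            calcium_score=calcium_score,
        )
        stenosed = replace(stenosed, lesions=[lesion])

        theta_applied = applied_theta if applied_theta is not None else config.reference_theta
        ct_value = ct_ffr(
            stenosed, lesion, theta_applied, offset=config.measurement_offset
        )
        reading, ge50, ge70 = cta_reading(degree, config.cta_reader_sd, rng)

        rows.append(
            {
                "vessel_id": vessel_id,
                "vessel_label": label,
                "ct_ffr": ct_value,
                "measured_ffr": u,
                "cta_percent_stenosis": reading,
                "cta_ge_50": ge50,
                "cta_ge_70": ge70,
                "true_degree": degree,
                "lesion_length": length,
                "plaque_volume": metrics.plaque_volume_mm3,
                "calcified_volume": calcified,
                "noncalcified_volume": noncalcified,
                "plaque_burden": metrics.plaque_burden_pct,
                "lumen_area": metrics.min_lumen_area_mm2,
                "lumen_diameter": metrics.min_lumen_diameter_mm,
                "calcium_score": calcium_score,
            }
        )
        trees[vessel_id] = (stenosed, lesion)

    return pd.DataFrame(rows, columns=COHORT_COLUMNS), trees


#: retrospective calibration design: (proximal diameter mm, degree %, lesion
#: length mm).  Two complementary severe archetypes — a long 75% lesion whose
#: pressure loss is viscosity-dominated and a focal 84% lesion dominated by
#: post-stenotic jet expansion — separate the linear from the quadratic loss
#: term, while the calibre spread 2.4-4.3 mm identifies the outlet
#: diameter exponent; moderate 55% lesions widen the degree span.
CALIBRATION_DESIGN = [
    (d0, deg, length)
    for (deg, length) in [(75.0, 65.0), (84.0, 4.0)]
    for d0 in (2.4, 3.3, 4.3)
]
CALIBRATION_DESIGN_MODERATE = [(2.4, 55.0, 20.0), (3.3, 55.0, 20.0), (4.3, 55.0, 20.0)]


def calibration_design_cases(
    n_cases: int = 80,
    reference_theta: BoundaryParams | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
):
    """Information-rich retrospective training set for parameter calibration.

    Builds ``n_cases`` vessels by cycling through :data:`CALIBRATION_DESIGN`
    (9 in 10 cases) and :data:`CALIBRATION_DESIGN_MODERATE` (1 in 10),
    computes each measured FFR from the reference model, and adds optional
    Gaussian measurement noise (truncated to (0, 1]).  Returns a list of
    TrainingCase.
    """
    from .calibration import TrainingCase

    theta = reference_theta or BoundaryParams()
    if noise_sd > 0 and rng is None:
        raise ValidationError("an rng is required when noise_sd > 0")
    cases = []
    n_moderate = max(0, n_cases // 10)
    plan = [CALIBRATION_DESIGN[i % len(CALIBRATION_DESIGN)] for i in range(n_cases - n_moderate)]
    plan += [CALIBRATION_DESIGN_MODERATE[i % 3] for i in range(n_moderate)]
    for d0, degree, length in plan:
        trunk_len = max(72.0, length + 12.0)
        trunk = make_segment(trunk_len, d0, 0.92 * d0, segment_id="prox", is_outlet=False)
        dist = make_segment(32.0, 0.88 * d0, 0.70 * d0, segment_id="dist",
                            parent_id="prox", is_outlet=True)
        side = make_segment(22.0, 0.68 * d0, 0.58 * d0, segment_id="side",
                            parent_id="prox", is_outlet=True)
        lesion = Lesion("prox", 6.0, length, degree)
        tree = apply_lesions(
            VesselTree.from_segments([trunk, dist, side], "LAD"), [lesion]
        )
        value = ct_ffr(tree, lesion, theta)
        if noise_sd > 0:
            value += rng.normal(0.0, noise_sd)
        value = float(min(max(value, 1e-6), 1.0))
        cases.append(TrainingCase(tree, lesion, value))
    return cases


def cohort_to_training_cases(
    cohort: pd.DataFrame, trees: Mapping[str, tuple[VesselTree, Lesion]]
):
    """Pair each cohort row with its tree as a calibration TrainingCase."""
    from .calibration import TrainingCase

    cases = []
    for _, row in cohort.iterrows():
        tree, lesion = trees[row["vessel_id"]]
        cases.append(TrainingCase(tree, lesion, float(row["measured_ffr"])))
    return cases
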