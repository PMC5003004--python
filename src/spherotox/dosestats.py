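"""Dose-response fitting and screening statistics.

The four-parameter logistic (4PL) model used throughout is

    y(d) = bottom + (top - bottom) / (1 + (d / IC50)^hill)

so y -> top as d -> 0 and y -> bottom as d -> infinity (hill > 0), and
y(IC50) = (top + bottom) / 2 identically. IC50 is fitted on the log
scale with standard errors from the covariance of the least-squares
fit; undefined standard errors and non-convergence are reported, never
silently dropped. Screening quality metrics (CV, Z'-factor),
sensitivity/predictivity tallies, and cross-assay IC50 comparisons
operate on fits or on censored benchmark outcomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .synthgen import CompoundRecord, Outcome


class FitRefusedError(ValueError):
    """Raised when the data cannot support a 4PL fit (e.g. <4 distinct doses)."""


def four_pl(dose, bottom: float, top: float, ic50: float, hill: float):
    """Evaluate the 4PL model; exact at dose 0 (returns top)."""
    dose = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(dose > 0, (dose / ic50) ** hill, 0.0)
    return bottom + (top - bottom) / (1.0 + ratio)


@dataclass
class DoseResponseFit:
    bottom: float
    top: float
    ic50_uM: float
    hill: float
    se_bottom: float | None = None
    se_top: float | None = None
    se_ic50_uM: float | None = None
    se_hill: float | None = None
    converged: bool = True
    at_bounds: bool = False
    residual_sd: float = float("nan")
    n_points: int = 0
    message: str = ""

    def predict(self, dose):
        return four_pl(dose, self.bottom, self.top, self.ic50_uM, self.hill)

    @property
    def amplitude(self) -> float:
        return abs(self.top - self.bottom)

    @property
    def has_ic50(self) -> bool:
        """Whether the fit supports a genuine IC50: converged, away from
        the parameter bounds, and with a fitted transition amplitude
        clearly above the residual noise (a near-flat series can
        otherwise "converge" onto an arbitrary midpoint)."""
        if not self.converged or self.at_bounds or not self.ic50_uM > 0:
            return False
        if math.isfinite(self.residual_sd) and self.residual_sd > 0:
            return self.amplitude > 3.0 * self.residual_sd
        return True


def fit_4pl(doses: Sequence[float], responses: Sequence[float],
            hill_max: float = 10.0) -> DoseResponseFit:
    """Least-squares 4PL fit.

    IC50 is parameterized as log(IC50) with bounds
    [min positive dose / 100, max dose x 100] and hill in (0, 10];
    starting values come from the response quartiles. Requires at least
    4 distinct doses. A fit whose IC50 or hill lands on a bound is
    flagged ``at_bounds`` (typical for flat, no-effect data) so it is
    never mistaken for a genuine IC50.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != responses.shape:
        raise FitRefusedError("doses and responses must have equal length")
    if not np.isfinite(responses).all() or not np.isfinite(doses).all():
        raise FitRefusedError("doses and responses must be finite")
    n_distinct = len(np.unique(doses))
    if n_distinct < 4:
        raise FitRefusedError(
            f"4PL fit needs >= 4 distinct doses, got {n_distinct}"
        )
    pos = doses[doses > 0]
    if len(pos) == 0:
        raise FitRefusedError("at least one positive dose is required")
    lo_ic, hi_ic = pos.min() / 100.0, doses.max() * 100.0

    ymin, ymax = float(responses.min()), float(responses.max())
    span = max(ymax - ymin, 1e-12)
    mid = 0.5 * (ymin + ymax)
    # initial ic50: positive dose whose mean response is nearest the midpoint
    dose_levels = np.unique(pos)
    level_means = np.array([responses[doses == d].mean() for d in dose_levels])
    ic0 = float(dose_levels[np.argmin(np.abs(level_means - mid))])

    def model(d, bottom, top, ln_ic50, hill):
        return four_pl(d, bottom, top, math.exp(ln_ic50), hill)

    p0 = [ymin, ymax, math.log(ic0), 1.0]
    bounds = (
        [ymin - 2 * span, ymin - 2 * span, math.log(lo_ic), 1e-3],
        [ymax + 2 * span, ymax + 2 * span, math.log(hi_ic), hill_max],
    )
    p0 = np.clip(p0, bounds[0], bounds[1])
    try:
        popt, pcov = optimize.curve_fit(
            model, doses, responses, p0=p0, bounds=bounds, maxfev=20000
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        return DoseResponseFit(
            bottom=float("nan"), top=float("nan"), ic50_uM=float("nan"),
            hill=float("nan"), converged=False, n_points=len(doses),
            message=f"fit did not converge: {exc}",
        )
    bottom, top, ln_ic50, hill = popt
    ic50 = math.exp(ln_ic50)
    resid = responses - model(doses, *popt)
    dof = max(len(doses) - 4, 1)
    residual_sd = float(np.sqrt(resid @ resid / dof))

    ses: list[float | None] = [None] * 4
    diag = np.diag(pcov)
    if np.all(np.isfinite(diag)):
        raw = np.sqrt(diag)
        ses = [float(s) if np.isfinite(s) else None for s in raw]
    se_ic50 = ic50 * ses[2] if ses[2] is not None else None

    eps = 1e-6
    at_bounds = (
        ln_ic50 <= bounds[0][2] + eps or ln_ic50 >= bounds[1][2] - eps
        or hill <= bounds[0][3] + eps or hill >= bounds[1][3] - eps
    )
    return DoseResponseFit(
        bottom=float(bottom), top=float(top), ic50_uM=float(ic50),
        hill=float(hill),
        se_bottom=ses[0], se_top=ses[1], se_ic50_uM=se_ic50, se_hill=ses[3],
        converged=True, at_bounds=bool(at_bounds),
        residual_sd=residual_sd, n_points=len(doses),
    )


@dataclass(frozen=True)
class OutcomeClassification:
    """Censored screening outcome for one compound x assay.

    ``ic50``: effect present and IC50 bracketed; ``gt_max``: effect at
    the top dose but IC50 not determined; ``no_tox``: no apparent effect
    up to the top dose tested.
    """

    kind: str  # one of {"ic50", "gt_max", "no_tox"}
    value_uM: float | None = None
    se_uM: float | None = None
    max_uM: float | None = None

    @property
    def detected(self) -> bool:
        return self.kind != "no_tox"


def classify_outcome(
    fit: DoseResponseFit | None,
    responses_by_dose: Mapping[float, Sequence[float]],
    max_tested_uM: float,
    effect_criterion: float = 0.30,
    alpha: float = 0.05,
) -> OutcomeClassification:
    """Classify a dose series into ic50 / gt_max / no_tox.

    A detectable effect requires at least an ``effect_criterion``
    relative decrease of the response at the top dose versus the
    vehicle control (dose 0; the fitted top is used when no control
    wells exist), significant at ``alpha`` by a two-sample t-test when
    replicate counts allow one. An ``ic50`` outcome additionally
    requires the IC50 to be bracketed by the data: the fit usable
    (:attr:`DoseResponseFit.has_ic50`), the estimate inside the tested
    range, and the top-dose response at or below half of the control —
    an effect seen only at the top dose without reaching half-kill is
    reported as ``gt_max``.
    """
    doses = sorted(responses_by_dose)
    if not doses:
        raise ValueError("responses_by_dose is empty")
    top_dose = max(doses)
    top_resp = np.asarray(responses_by_dose[top_dose], dtype=float)
    if 0.0 in responses_by_dose:
        ctrl = np.asarray(responses_by_dose[0.0], dtype=float)
    elif fit is not None and fit.converged:
        ctrl = np.asarray([fit.top])
    else:
        ctrl = np.asarray(responses_by_dose[min(doses)], dtype=float)
    ctrl_mean = float(ctrl.mean())
    decrease = 1.0 - float(top_resp.mean()) / ctrl_mean if ctrl_mean else 0.0
    significant = True
    if len(ctrl) >= 2 and len(top_resp) >= 2:
        _, p = stats.ttest_ind(ctrl, top_resp, equal_var=False)
        significant = bool(p < alpha)
    effect = decrease >= effect_criterion and significant
    if not effect:
        return OutcomeClassification(kind="no_tox", max_uM=max_tested_uM)
    bracketed = float(top_resp.mean()) <= 0.5 * ctrl_mean
    if (bracketed and fit is not None and fit.has_ic50
            and fit.ic50_uM <= max_tested_uM):
        return OutcomeClassification(
            kind="ic50", value_uM=fit.ic50_uM, se_uM=fit.se_ic50_uM,
            max_uM=max_tested_uM,
        )
    return OutcomeClassification(kind="gt_max", max_uM=max_tested_uM)


# --------------------------------------------------------------------------
# screening quality metrics


def cv(values: Sequence[float]) -> float:
    """Coefficient of variation, 100 x sample SD / mean (percent)."""
    vals = np.asarray(values, dtype=float)
    if len(vals) < 2:
        raise ValueError("CV needs at least 2 values")
    mean = vals.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * vals.std(ddof=1) / mean)


def cv_from_mean_sd(mean: float, sd: float) -> float:
    """CV (percent) from a reported mean and standard deviation."""
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return 100.0 * sd / mean


def zprime(pos_values: Sequence[float], neg_values: Sequence[float]) -> float:
    """Z'-factor, 1 - 3(σ+ + σ-)/|μ+ - μ-|; NaN when the means coincide."""
    pos = np.asarray(pos_values, dtype=float)
    neg = np.asarray(neg_values, dtype=float)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("Z' needs at least 2 values per group")
    sep = abs(pos.mean() - neg.mean())
    if sep == 0:
        return float("nan")
    return float(1.0 - 3.0 * (pos.std(ddof=1) + neg.std(ddof=1)) / sep)


# --------------------------------------------------------------------------
# cross-assay comparisons


@dataclass(frozen=True)
class FitComparison:
    ratio: float | None  # a / b
    p_value: float | None
    significant: bool | None
    indeterminate: bool = False


def compare_ic50(a_value: float, a_se: float | None,
                 b_value: float | None, b_se: float | None,
                 alpha: float = 0.05) -> FitComparison:
    """Two-sided z-test on log-IC50 with fit standard errors propagated
    to the log scale. Missing values or SEs give an indeterminate
    comparison (mirroring tables where uncertainties were undefined)."""
    if not a_value or not b_value:
        return FitComparison(None, None, None, indeterminate=True)
    ratio = a_value / b_value
    if a_se is None or b_se is None:
        return FitComparison(ratio, None, None, indeterminate=True)
    se_log = math.sqrt((a_se / a_value) ** 2 + (b_se / b_value) ** 2)
    if se_log == 0:
        p = 0.0 if a_value != b_value else 1.0
    else:
        z = abs(math.log(a_value) - math.log(b_value)) / se_log
        p = float(2.0 * stats.norm.sf(z))
    return FitComparison(ratio, p, bool(p < alpha))


def compare_fits(a: DoseResponseFit, b: DoseResponseFit,
                 alpha: float = 0.05) -> FitComparison:
    """Compare two fitted IC50s (ratio a/b, log-scale z-test)."""
    if not (a.has_ic50 and b.has_ic50):
        return FitComparison(None, None, None, indeterminate=True)
    return compare_ic50(a.ic50_uM, a.se_ic50_uM, b.ic50_uM, b.se_ic50_uM, alpha)


def sensitivity_predictivity(records: Sequence[CompoundRecord],
                             assay: str) -> dict:
    """Screening sensitivity and predictivity for one assay.

    sensitivity = % of known-toxic compounds (every class except the
    negative controls) with a detected effect; predictivity = % of
    negative controls correctly negative. "n.d." rows are not evaluable
    and enter neither numerator nor denominator. Percentages are
    rounded to the nearest whole percent.
    """
    rows = [r for r in records if r.assay == assay]
    if not rows:
        raise ValueError(f"no records for assay {assay!r}")
    toxic = [r for r in rows
             if not r.is_negative_control and r.outcome.kind != "nd"]
    negative = [r for r in rows
                if r.is_negative_control and r.outcome.kind != "nd"]
    det = sum(r.outcome.detected for r in toxic)
    neg_ok = sum(not r.outcome.detected for r in negative)
    return {
        "sensitivity_pct": round(100.0 * det / len(toxic)) if toxic else None,
        "predictivity_pct": round(100.0 * neg_ok / len(negative)) if negative else None,
        "n_toxic": len(toxic),
        "n_toxic_detected": det,
        "n_negative": len(negative),
        "n_negative_correct": neg_ok,
    }


def fold_sensitivity(records: Sequence[CompoundRecord],
                     compound_set: Sequence[str],
                     assay_a: str, assay_b: str) -> dict:
    """Per-compound IC50 ratio assay_b / assay_a and the minimum ratio.

    Measures how much more sensitive assay_a is; requires a numeric
    IC50 in both assays for every compound in the set.
    """
    by_key = {(r.name, r.assay): r for r in records}
    ratios = {}
    for name in compound_set:
        a = by_key.get((name, assay_a))
        b = by_key.get((name, assay_b))
        if a is None or b is None:
            raise KeyError(f"compound {name!r} missing from one of the assays")
        if a.outcome.value_uM is None or b.outcome.value_uM is None:
            raise ValueError(
                f"compound {name!r} lacks a numeric IC50 in both assays"
            )
        ratios[name] = b.outcome.value_uM / a.outcome.value_uM
    return {"ratios": ratios, "min_ratio": min(ratios.values())}


def cross_assay_comparison(records: Sequence[CompoundRecord],
                           assay_a: str, assay_b: str,
                           alpha: float = 0.05) -> "pd.DataFrame":
    """Per-compound comparison table between two assays: IC50s, ratio
    (assay_b / assay_a), and log-scale z-test significance where both
    standard errors are defined."""
    import pandas as pd

    by_assay: dict[str, dict[str, CompoundRecord]] = {}
    for r in records:
        by_assay.setdefault(r.assay, {})[r.name] = r
    rows = []
    for name, ra in by_assay.get(assay_a, {}).items():
        rb = by_assay.get(assay_b, {}).get(name)
        if rb is None:
            continue
        oa, ob = ra.outcome, rb.outcome
        comp = compare_ic50(ob.value_uM, ob.se_uM, oa.value_uM, oa.se_uM, alpha)
        rows.append({
            "compound": name,
            "class": ra.compound_class,
            f"ic50_{assay_a}": oa.value_uM,
            f"ic50_{assay_b}": ob.value_uM,
            "ratio_b_over_a": comp.ratio,
            "p_value": comp.p_value,
            "significant": comp.significant,
            "indeterminate": comp.indeterminate,
        })
    return pd.DataFrame(rows)
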