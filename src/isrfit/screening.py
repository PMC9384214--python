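"""Leave-one-timepoint-out screening for suspect OGTT measurements.

A single corrupted glucose draw (e.g., a spurious dip at 60 min) can
degrade the whole subject fit because the interpolated glucose drives the
secretion model.  Screening removes one interior sample time (glucose,
insulin and c-peptide together), refits with identical settings and seed,
and asks whether all three goodness-of-fit criteria — insulin misfit,
c-peptide misfit, and the CSR~ISR line misfit — strictly improved.
Simultaneous improvement of the three independent criteria is the outlier
signature; removing a clean point discards information and typically
leaves them unchanged or slightly worse.

Because the reported root-sum-square metrics carry no 1/N, removing a
point shrinks them almost surely regardless of data quality.  The
improvement verdict therefore compares residual *scales* adjusted for
sample size and model degrees of freedom, sqrt(SS / (N - p)), which are
comparable across records of different length; the raw reports and their
deltas are returned alongside so users can apply their own threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np

from .estimation import EstimationError, FitConfig, fit_subject
from .metrics import FitReport, evaluate_subject
from .preprocessing import OGTTRecord, drop_timepoint

__all__ = ["ScreenResult", "screen_timepoint", "screen_all", "SCREEN_N_STARTS"]

#: reduced ensemble size used inside screening (two full subject fits per
#: screened point).
SCREEN_N_STARTS = 100

_RMS_FIELDS = ("rms_insulin", "rms_cpeptide", "rms_csr_isr")


@dataclass(frozen=True)
class ScreenResult:
    """Effect of removing one sample time on the three fit criteria.

    ``baseline`` or ``without_point`` is ``None`` when the corresponding
    subject fit produced no accepted solution (every start excluded at a
    bound): a record so corrupted that no interior optimum exists.  Such a
    fit counts as infinitely bad, so a baseline failure that is cured by
    the removal flags the point.
    """

    timepoint: float
    baseline: Optional[FitReport]
    without_point: Optional[FitReport]
    improved_all: bool
    #: change of the raw root-sum-square reports (without - baseline)
    deltas: Dict[str, float]
    #: change of the size/df-adjusted residual scales driving ``improved_all``
    adjusted_deltas: Dict[str, float]

    @property
    def total_delta(self) -> float:
        return float(sum(self.adjusted_deltas.values()))


def _n_model_params(kind: str) -> int:
    return 4 if kind == "single" else 5


def _adjusted_scales(rec: OGTTRecord, report: FitReport, kind: str) -> Dict[str, float]:
    """Residual scale sqrt(SS) / sqrt(N - p) per criterion, comparable across N.

    The normalized reports equal sqrt(SS)/norm; multiplying back by the
    normalizer is unnecessary because it is common to both records only
    approximately — instead the adjustment divides each report by
    sqrt(N - p) with the criterion's own N and parameter count (4 or 5
    model parameters for the trajectories, 2 for the fitted line).
    """
    p_model = _n_model_params(kind)
    n_i = int(np.sum(np.isfinite(rec.insulin)))
    n_c = int(np.sum(np.isfinite(rec.cpeptide)))
    n_line = rec.times.size
    return {
        "rms_insulin": report.rms_insulin / np.sqrt(n_i - p_model),
        "rms_cpeptide": report.rms_cpeptide / np.sqrt(n_c - p_model),
        "rms_csr_isr": report.rms_csr_isr / np.sqrt(n_line - 2),
    }


def _screen_config(config: Optional[FitConfig]) -> FitConfig:
    if config is None:
        return FitConfig(n_starts=SCREEN_N_STARTS)
    return config


def screen_timepoint(rec: OGTTRecord, t: float, config: Optional[FitConfig] = None) -> ScreenResult:
    """Refit with and without the sample at ``t`` and compare fit quality.

    ``t`` must be an interior sample time — the first and last draws anchor
    the glucose interpolant and are never screened.  Both fits share the
    same configuration and seed so the comparison isolates the removed
    point.
    """
    config = _screen_config(config)
    if np.isclose(t, rec.times[0]) or np.isclose(t, rec.times[-1]):
        raise ValueError("endpoint sample times cannot be screened (interpolation would extrapolate)")
    reduced = drop_timepoint(rec, t)
    baseline = _report_or_none(rec, config)
    without = _report_or_none(reduced, config)
    inf_scales = {name: math.inf for name in _RMS_FIELDS}
    base_scales = inf_scales if baseline is None else _adjusted_scales(rec, baseline, config.model_kind)
    red_scales = inf_scales if without is None else _adjusted_scales(reduced, without, config.model_kind)
    adjusted = {name: red_scales[name] - base_scales[name] for name in _RMS_FIELDS}
    if baseline is None and without is not None:
        improved_all = True  # unfittable record cured by the removal
    elif without is None:
        improved_all = False
    else:
        improved_all = all(d < 0 for d in adjusted.values())
    deltas = {
        name: (math.inf if without is None else -math.inf) if (baseline is None or without is None)
        else getattr(without, name) - getattr(baseline, name)
        for name in _RMS_FIELDS
    }
    if baseline is None and without is None:
        deltas = {name: math.nan for name in _RMS_FIELDS}
        adjusted = dict(deltas)
    return ScreenResult(
        timepoint=float(t),
        baseline=baseline,
        without_point=without,
        improved_all=improved_all,
        deltas=deltas,
        adjusted_deltas=adjusted,
    )


def _report_or_none(rec: OGTTRecord, config: FitConfig) -> Optional[FitReport]:
    try:
        ens_i, ens_c = fit_subject(rec, config)
        return evaluate_subject(rec, ens_i, ens_c)
    except EstimationError:
        return None


def screen_all(rec: OGTTRecord, config: Optional[FitConfig] = None) -> List[ScreenResult]:
    """Screen every interior sample time, most-improving first.

    Results are ordered by the summed change of the three adjusted
    residual scales (largest decrease first), so a single corrupted point
    surfaces at the top of the list.  Deterministic for a fixed config
    seed.
    """
    config = _screen_config(config)
    results = [screen_timepoint(rec, t, config) for t in rec.times[1:-1]]

    def key(r: ScreenResult):
        # flagged points first, then by summed improvement; NaN (both fits
        # failed) last
        total = r.total_delta
        return (not r.improved_all, math.inf if math.isnan(total) else total)

    return sorted(results, key=key)
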