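"""Goodness-of-fit metrics and the molar-ratio consistency check.

Insulin and c-peptide are co-secreted by the beta cell in a 1:1 molar
ratio, which in the working units (ISR in uU/ml/min, CSR in ng/ml/min)
corresponds to a CSR/ISR slope of 0.056 ng/uU.  Because the two species
are fitted independently, the linear relation between their inferred
secretion rates is an external validation of the whole inference; a slope
above the molar constant is read as first-pass hepatic insulin extraction
alpha_h = 1 - 0.056 / slope.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from typing import NamedTuple, Tuple

import numpy as np
from scipy import stats
from statsmodels.distributions.empirical_distribution import ECDF

from .estimation import FitEnsemble
from .models import convert_glucose
from .preprocessing import OGTTRecord

__all__ = [
    "CSR_PER_ISR",
    "FitReport",
    "HepaticAbsorption",
    "rms_error",
    "csr_isr_fit",
    "hepatic_absorption",
    "isr_at",
    "ecdf",
    "evaluate_subject",
]

#: 1:1 molar secretion of c-peptide (ng/ml) per insulin (uU/ml), used as a
#: fixed conversion constant.
CSR_PER_ISR = 0.056

#: default reference glucose (mg/dl) at which the ISR is evaluated to
#: compare subjects.
REFERENCE_GLUCOSE_MGDL = 140.0


def rms_error(measured, modeled, normalizer: str = "mean") -> float:
    """Normalized root-sum-square error between a measured and a modeled series.

    The root of the summed squared differences is divided by the mean
    (trajectory fits) or the maximum (secretion-relation fit) of the
    measured reference series.  Note there is no 1/N inside the root, so
    values are only comparable across series of equal length.
    """
    measured = np.asarray(measured, dtype=float)
    modeled = np.asarray(modeled, dtype=float)
    if measured.shape != modeled.shape or measured.size < 1:
        raise ValueError("series must be non-empty and of equal length")
    if normalizer == "mean":
        norm = float(np.mean(measured))
    elif normalizer == "max":
        norm = float(np.max(measured))
    else:
        raise ValueError(f"unknown normalizer {normalizer!r}")
    if norm <= 0:
        raise ValueError("normalizer of the reference series must be > 0")
    return float(np.sqrt(np.sum((measured - modeled) ** 2)) / norm)


def csr_isr_fit(isr, csr) -> Tuple[float, float, float]:
    """Ordinary least-squares line CSR ~ slope * ISR + intercept.

    Both series must be evaluated at the same measurement times.  Returns
    ``(slope, intercept, rms)`` where rms is the root-sum-square misfit of
    the line normalized by the maximum CSR value.
    """
    isr = np.asarray(isr, dtype=float)
    csr = np.asarray(csr, dtype=float)
    if isr.shape != csr.shape or isr.size < 3:
        raise ValueError("need >= 3 paired (ISR, CSR) values")
    if np.ptp(isr) == 0:
        raise ValueError("degenerate fit: ISR series has zero variance")
    fit = stats.linregress(isr, csr)
    line = fit.slope * isr + fit.intercept
    return float(fit.slope), float(fit.intercept), rms_error(csr, line, normalizer="max")


class HepaticAbsorption(NamedTuple):
    alpha_h: float
    sub_molar: bool  # slope below the molar constant; alpha_h clipped to 0


def hepatic_absorption(slope: float) -> HepaticAbsorption:
    """First-pass hepatic extraction fraction implied by a CSR/ISR slope.

    C-peptide escapes hepatic degradation while a fraction alpha_h of
    newly secreted insulin does not, so the observed slope is
    0.056 / (1 - alpha_h) and alpha_h = 1 - 0.056 / slope, clipped to
    [0, 1).  A slope below 0.056 has no hepatic reading and returns 0 with
    the ``sub_molar`` flag set.
    """
    if not (np.isfinite(slope) and slope > 0):
        raise ValueError(f"slope must be finite and > 0, got {slope}")
    if slope < CSR_PER_ISR:
        return HepaticAbsorption(0.0, True)
    return HepaticAbsorption(float(1.0 - CSR_PER_ISR / slope), False)


def isr_at(g_ref: float, ensemble: FitEnsemble) -> Tuple[float, float]:
    """Mean +/- SD secretion rate at a reference glucose over the accepted fits.

    ``g_ref`` must be in the glucose unit the ensemble was fitted in.
    Warns when the reference exceeds the subject's maximum measured
    glucose, where the sigmoid is extrapolated beyond the expressed range.
    """
    if ensemble.n_accepted == 0:
        raise ValueError("ensemble has no accepted solutions")
    if g_ref > ensemble.max_measured_glucose:
        warnings.warn(
            f"reference glucose {g_ref} exceeds the maximum measured value "
            f"{ensemble.max_measured_glucose}; secretion is extrapolated",
            stacklevel=2,
        )
    samples = ensemble.secretion_samples(g_ref)
    sd = float(np.std(samples, ddof=1)) if samples.size > 1 else 0.0
    return float(np.mean(samples)), sd


def ecdf(values) -> ECDF:
    """Right-continuous empirical CDF of a sample (F(max) = 1, F(x < min) = 0)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("ecdf needs a non-empty sample")
    return ECDF(values)


@dataclass(frozen=True)
class FitReport:
    """Per-subject goodness-of-fit and molar-ratio summary."""

    rms_insulin: float
    rms_cpeptide: float
    rms_csr_isr: float
    slope: float
    intercept: float
    alpha_h: float
    sub_molar: bool
    isr_at_ref: float
    isr_at_ref_sd: float
    g_ref: float

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload


def evaluate_subject(
    rec: OGTTRecord,
    insulin: FitEnsemble,
    cpeptide: FitEnsemble,
    g_ref_mgdl: float = REFERENCE_GLUCOSE_MGDL,
) -> FitReport:
    """Assemble the three normalized RMS errors and the CSR~ISR line for one subject.

    Trajectory errors compare measured concentrations with the ensemble-mean
    model output at the measurement times; the secretion relation pairs the
    ensemble-mean ISR and CSR at the record's sample times.
    """
    ti, zi = rec.species_values("insulin")
    tc, zc = rec.species_values("cpeptide")
    mask_i = np.isfinite(rec.insulin)
    mask_c = np.isfinite(rec.cpeptide)
    rms_i = rms_error(zi, insulin.output_at_times_mean[mask_i])
    rms_c = rms_error(zc, cpeptide.output_at_times_mean[mask_c])
    slope, intercept, rms_sc = csr_isr_fit(
        insulin.secretion_at_times_mean, cpeptide.secretion_at_times_mean
    )
    hep = hepatic_absorption(slope)
    g_ref = convert_glucose(g_ref_mgdl, "mg/dl", rec.glucose_unit)
    isr_ref, isr_ref_sd = isr_at(g_ref, insulin)
    return FitReport(
        rms_insulin=rms_i,
        rms_cpeptide=rms_c,
        rms_csr_isr=rms_sc,
        slope=slope,
        intercept=intercept,
        alpha_h=hep.alpha_h,
        sub_molar=hep.sub_molar,
        isr_at_ref=isr_ref,
        isr_at_ref_sd=isr_ref_sd,
        g_ref=g_ref,
    )
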