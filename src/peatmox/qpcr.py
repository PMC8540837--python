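"""Absolute qPCR quantification of pmoA transcripts.

A genomic-DNA dilution series (decadal, e.g. 7.15e6 down to 7.15 copies
per reaction) yields a standard curve Cq = intercept + slope*log10(copies);
sample Cq values are inverted through the curve and scaled to copies per
gram dry soil.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gas_kinetics import SoilContext, ValidationError, _ols

logger = logging.getLogger(__name__)

#: default standard range: seven decades, 7.15e6 .. 7.15 copies per reaction
DEFAULT_STANDARD_LEVELS = 7.15 * 10.0 ** np.arange(6, -1, -1)


@dataclass
class DilutionStandard:
    """Replicated (copies, Cq) observations of a dilution series."""

    copies: np.ndarray
    cq: np.ndarray

    def __post_init__(self) -> None:
        self.copies = np.asarray(self.copies, dtype=float)
        self.cq = np.asarray(self.cq, dtype=float)
        if self.copies.shape != self.cq.shape:
            raise ValidationError("copies and cq must have equal length")
        if np.any(self.copies <= 0):
            raise ValidationError("copy numbers must be positive")
        if not np.all(np.isfinite(self.cq)):
            raise ValidationError("Cq values must be finite")
        if len(np.unique(self.copies)) < 2:
            raise ValidationError("need at least two distinct copy levels")


@dataclass(frozen=True)
class StandardCurve:
    """Fitted log-linear standard curve.

    efficiency = 10**(-1/slope) - 1, i.e. 1.0 (100%) at the ideal decadal
    slope of -log2(10) = -3.3219 cycles per decade.
    """

    slope: float
    intercept: float
    r_squared: float
    copies_min: float
    copies_max: float

    @property
    def efficiency(self) -> float:
        return 10.0 ** (-1.0 / self.slope) - 1.0

    @property
    def valid(self) -> bool:
        return self.slope < 0


def fit_standard_curve(standard: DilutionStandard) -> StandardCurve:
    """OLS of mean Cq per level on log10(copies).

    Replicates are averaged per copy level before fitting, so replicated
    and pre-averaged inputs give the same curve. A non-negative slope is
    flagged invalid (curve.valid is False) but still returned.
    """
    levels = np.unique(standard.copies)
    mean_cq = np.array([standard.cq[standard.copies == c].mean() for c in levels])
    slope, intercept, r2, _ = _ols(np.log10(levels), mean_cq)
    curve = StandardCurve(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        copies_min=float(levels.min()),
        copies_max=float(levels.max()),
    )
    if not curve.valid:
        logger.warning("standard curve slope %.3f >= 0: curve flagged invalid", slope)
    return curve


@dataclass(frozen=True)
class Quantification:
    copies_per_reaction: float
    copies_per_g_dw: float | None
    extrapolated: bool


def quantify(
    cq_mean: float,
    curve: StandardCurve,
    elution_and_dilution_factor: float = 1.0,
    soil: SoilContext | None = None,
    template_mass_ng: float | None = None,
) -> Quantification:
    """Invert a mean Cq through the standard curve.

    copies_per_reaction = 10**((cq - intercept) / slope); the user-supplied
    elution_and_dilution_factor collects the extraction/elution/dilution
    chain from reaction to soil; dividing by the dry mass gives copies per
    gram dry soil. Cq values outside the standard's range are returned but
    flagged extrapolated. template_mass_ng is carried as metadata only.
    """
    if not curve.valid:
        raise ValidationError("cannot quantify with an invalid standard curve")
    copies = 10.0 ** ((cq_mean - curve.intercept) / curve.slope)
    extrapolated = not (
        curve.copies_min * (1 - 1e-9) <= copies <= curve.copies_max * (1 + 1e-9)
    )
    if extrapolated:
        logger.warning(
            "Cq %.2f -> %.3g copies lies outside the standard range [%.3g, %.3g]",
            cq_mean, copies, curve.copies_min, curve.copies_max,
        )
    per_g = None
    if soil is not None:
        per_g = copies * elution_and_dilution_factor / soil.dry_mass
    return Quantification(
        copies_per_reaction=copies, copies_per_g_dw=per_g, extrapolated=extrapolated
    )


def check_negative_controls(cq_values, cutoff: float = 35.0) -> bool:
    """True when all no-template controls are non-detect or above the cutoff."""
    cq = np.asarray(list(cq_values), dtype=float)
    clean = bool(np.all(np.isnan(cq) | (cq >= cutoff)))
    if not clean:
        logger.warning("negative control amplified below Cq %.1f: possible contamination", cutoff)
    return clean


def quantify_samples(
    samples: pd.DataFrame,
    curve: StandardCurve,
    elution_and_dilution_factor: float = 1.0,
    soils: dict[str, SoilContext] | None = None,
) -> pd.DataFrame:
    """Quantify a replicated sample table (columns sample_id, cq).

    Replicate Cq values are arithmetically averaged per sample before
    inversion. Returns sample_id, cq_mean, copies_per_reaction,
    copies_per_gdw (when a SoilContext is supplied), extrapolated.
    """
    if not {"sample_id", "cq"}.issubset(samples.columns):
        raise ValidationError("samples table needs columns sample_id, cq")
    rows = []
    for sample_id, grp in samples.groupby("sample_id", sort=False):
        cq_mean = float(grp["cq"].mean())
        soil = (soils or {}).get(sample_id)
        q = quantify(cq_mean, curve, elution_and_dilution_factor, soil)
        rows.append(
            {
                "sample_id": sample_id,
                "cq_mean": cq_mean,
                "n_replicates": len(grp),
                "copies_per_reaction": q.copies_per_reaction,
                "copies_per_gdw": q.copies_per_g_dw,
                "extrapolated": q.extrapolated,
            }
        )
    return pd.DataFrame(rows)
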