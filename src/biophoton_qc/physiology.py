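"""Physiological stress indices from raw assay readings.

Three indices quantify leaf stress state:

* photosynthetic pigment contents from extract absorbances at 474/642/665 nm,
  using the spectrophotometric equations

      Ca = 9.99*A665 - 0.0872*A642            (chlorophyll a, mg/L)
      Cb = 17.7*A642 - 3.04*A665              (chlorophyll b, mg/L)
      Cc = 4.92*A474 - 0.0255*Ca - 0.225*Cb   (carotenoids,  mg/L)

  converted to mg per g fresh leaf as content = C * V / m;

* relative electrical conductivity (electrolyte leakage),
  REC = (E2 - E1)/(E3 - E1), where E1, E2, E3 are the conductivities of
  blank water, the leaf-disc soak, and the same soak after boiling;

* mitochondrial ROS production rate v = 10*(k1 - k2)/g, with k1, k2 the
  least-squares slopes of DCFH-DA fluorescence against time for the sample
  and blank tubes and g the fresh mass in grams (the fluorescence unit "u"
  is instrument-defined and carried symbolically, giving v in u/s/g).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import InsufficientDataError, ParameterDomainError

__all__ = [
    "PigmentAssay", "PigmentContents", "RECAssay", "ROSAssay",
    "pigment_contents", "relative_conductivity", "ros_rate",
]


@dataclass
class PigmentAssay:
    """Absorbance readings of one pigment extraction.

    V is the extract volume in litres (protocol: 15 mL ethanol-acetone for
    0.1000 g of crushed leaf).
    """

    A474: float
    A642: float
    A665: float
    V: float = 0.015
    mass: float = 0.1

    def __post_init__(self) -> None:
        if min(self.A474, self.A642, self.A665) < 0:
            raise ParameterDomainError("absorbances must be non-negative")
        if self.V <= 0 or self.mass <= 0:
            raise ParameterDomainError("V and mass must be positive")


@dataclass(frozen=True)
class PigmentContents:
    """Pigment contents in mg per g fresh mass (concentrations in mg/L)."""

    Ca: float
    Cb: float
    Cc: float
    chlorophyll_a: float
    chlorophyll_b: float
    total_chlorophyll: float
    carotenoid: float
    total_pigment: float


def pigment_contents(assay: PigmentAssay) -> PigmentContents:
    """Pigment concentrations and per-mass contents from one extraction.

    A negative computed concentration (possible for unusual absorbance
    combinations) is reported with a warning, never clamped.
    """
    Ca = 9.99 * assay.A665 - 0.0872 * assay.A642
    Cb = 17.7 * assay.A642 - 3.04 * assay.A665
    Cc = 4.92 * assay.A474 - 0.0255 * Ca - 0.225 * Cb
    if min(Ca, Cb, Cc) < 0:
        warnings.warn("negative pigment concentration computed; reported unclamped",
                      stacklevel=2)
    to_content = assay.V / assay.mass  # mg/L -> mg/g
    a, b, c = Ca * to_content, Cb * to_content, Cc * to_content
    return PigmentContents(Ca=Ca, Cb=Cb, Cc=Cc,
                           chlorophyll_a=a, chlorophyll_b=b,
                           total_chlorophyll=a + b, carotenoid=c,
                           total_pigment=a + b + c)


@dataclass
class RECAssay:
    """Conductivity triplet: E1 blank water, E2 sample soak, E3 after boiling."""

    E1: float
    E2: float
    E3: float


def relative_conductivity(assay: RECAssay) -> float:
    """Electrolyte-leakage fraction REC = (E2 - E1)/(E3 - E1).

    Lies in [0, 1] whenever E1 <= E2 <= E3 (boiling releases all
    electrolytes, so E3 bounds E2)."""
    if assay.E3 <= assay.E1:
        raise ParameterDomainError("E3 must exceed E1 (boiled conductivity bounds blank)")
    return (assay.E2 - assay.E1) / (assay.E3 - assay.E1)


@dataclass
class ROSAssay:
    """Fluorescence-vs-time readings for the sample and blank tubes.

    Each point sequence is (time s, fluorescence intensity); g is the
    fresh sample mass in grams.
    """

    sample_points: np.ndarray   # shape (n, 2)
    blank_points: np.ndarray    # shape (k, 2)
    g: float

    def __post_init__(self) -> None:
        self.sample_points = np.atleast_2d(np.asarray(self.sample_points, dtype=float))
        self.blank_points = np.atleast_2d(np.asarray(self.blank_points, dtype=float))
        if self.g <= 0:
            raise ParameterDomainError("sample mass g must be positive")


def _ols_slope(points: np.ndarray) -> float:
    if points.shape[0] < 2:
        raise InsufficientDataError("need at least 2 fluorescence time points per tube")
    res = stats.linregress(points[:, 0], points[:, 1])
    return float(res.slope)


def ros_rate(assay: ROSAssay) -> float:
    """Mitochondrial ROS production rate v = 10*(k1 - k2)/g (u/s/g).

    k1 and k2 are ordinary-least-squares slopes (with intercept) of the
    sample- and blank-tube fluorescence against time."""
    k1 = _ols_slope(assay.sample_points)
    k2 = _ols_slope(assay.blank_points)
    return 10.0 * (k1 - k2) / assay.g
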