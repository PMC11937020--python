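"""Broth-microdilution MIC modelling and endpoint calling.

A 96-well dilution series halves the drug concentration from well to well
(1024, 512, ..., 8 ug/mL in the standard eight-well layout).  After
incubation, the minimum inhibitory concentration (MIC) is read from OD600:
the endpoint is 80% of the growth (positive-control) density, and the MIC
is the lowest concentration whose negative-control-corrected OD falls
below that endpoint.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .core import InvalidPlateError, ParameterDomainError

__all__ = ["MicPlate", "MicCall", "MicSummary", "dilution_ladder", "call_mic", "summarize_mic"]


def dilution_ladder(top: float, n_wells: int) -> np.ndarray:
    """Two-fold descending concentration series: top, top/2, ..., top/2^(n-1)."""
    if top <= 0:
        raise ParameterDomainError("top concentration must be positive")
    if n_wells < 1:
        raise ParameterDomainError("need at least one well")
    return top / 2.0 ** np.arange(n_wells, dtype=float)


@dataclass
class MicPlate:
    """One replicate dilution series with its growth and sterility controls."""

    concentrations: np.ndarray      # ug/mL, strictly two-fold descending
    od_wells: np.ndarray            # OD600 per drug well, aligned with concentrations
    od_positive: float              # growth control (bacteria, no drug)
    od_negative: float              # sterility control (drug, no bacteria)
    organism: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        od = np.asarray(self.od_wells, dtype=float)
        if conc.size != od.size or conc.size == 0:
            raise InvalidPlateError("concentrations and od_wells must align and be non-empty")
        if conc.size > 1 and not np.allclose(conc[:-1] / conc[1:], 2.0):
            raise InvalidPlateError("ladder must be exactly two-fold descending")
        if np.any(od < 0) or self.od_positive < 0 or self.od_negative < 0:
            raise InvalidPlateError("OD values must be non-negative")
        self.concentrations = conc
        self.od_wells = od


@dataclass(frozen=True)
class MicCall:
    """A called MIC: value in ug/mL with a censoring qualifier.

    qualifier "=" is an in-range call, ">" means no tested concentration
    inhibited (value = top of ladder), "<=" means every tested
    concentration inhibited (value = bottom of ladder).
    """

    value: float
    qualifier: str = "="

    def __str__(self) -> str:
        return f"{self.qualifier if self.qualifier != '=' else ''}{self.value:g}"


def call_mic(plate: MicPlate, endpoint_fraction: float = 0.8, rule: str = "threshold") -> MicCall:
    """Call the MIC from per-well OD600 readings.

    With the default ``"threshold"`` rule the MIC is the lowest
    concentration whose corrected OD (well minus sterility control) is
    below ``endpoint_fraction`` times the corrected growth-control OD.
    If no well qualifies the call is "> top"; if every well qualifies it is
    "<= bottom".  The alternative ``"closest"`` rule returns the
    concentration whose corrected OD is nearest the endpoint (a literal
    reading of the endpoint phrasing; not monotone, kept for comparison).
    """
    if not 0 < endpoint_fraction < 1:
        raise ParameterDomainError("endpoint_fraction must lie in (0, 1)")
    corrected_pos = plate.od_positive - plate.od_negative
    if corrected_pos <= 0:
        raise InvalidPlateError("growth control must exceed sterility control")
    corrected = plate.od_wells - plate.od_negative
    threshold = endpoint_fraction * corrected_pos

    if rule == "closest":
        idx = int(np.argmin(np.abs(corrected - threshold)))
        return MicCall(float(plate.concentrations[idx]))
    if rule != "threshold":
        raise ValueError("rule must be 'threshold' or 'closest'")

    qualifying = corrected < threshold
    if not qualifying.any():
        return MicCall(float(plate.concentrations[0]), ">")
    lowest = float(plate.concentrations[qualifying].min())
    if qualifying.all() and lowest == float(plate.concentrations[-1]):
        return MicCall(lowest, "<=")
    return MicCall(lowest)


@dataclass(frozen=True)
class MicSummary:
    consensus: float
    qualifier: str
    low: float
    high: float
    n: int


def summarize_mic(calls: list) -> MicSummary:
    """Consensus over replicate MIC calls: modal value, ties broken toward
    the higher concentration; the min-max range is retained."""
    if not calls:
        raise ValueError("need at least one replicate MIC")
    calls = [c if isinstance(c, MicCall) else MicCall(float(c)) for c in calls]
    values = [c.value for c in calls]
    counts = Counter(values)
    top_count = max(counts.values())
    consensus = max(v for v, k in counts.items() if k == top_count)
    quals = {c.qualifier for c in calls if c.value == consensus}
    qualifier = ">" if quals == {">"} else ("<=" if quals == {"<="} else "=")
    if len({c.qualifier for c in calls}) > 1:
        warnings.warn("mixed censoring qualifiers among replicate MICs", stacklevel=2)
    return MicSummary(consensus=consensus, qualifier=qualifier,
                      low=min(values), high=max(values), n=len(calls))
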