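"""Shared domain types and error hierarchy.

The central in-memory object is :class:`PhotonTrace`, a binned photon-count
time series as produced by a single-photon-counting detector: one integer
count per fixed-width time bin.  Three run kinds occur in a measurement
session: a delayed-luminescence (DL) decay recorded after light stimulation,
a spontaneous-photon-emission (SPE) steady-state run, and an instrument
background (dark-count) run with no sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

RUN_KINDS = ("DL", "SPE", "background")

#: default DL decay window (s)
DL_DURATION = 300.0
#: default number of 1-s SPE detection points
SPE_BINS = 600
#: default background run length (s); background is recorded for 10 min
BACKGROUND_BINS = 600


class ParameterDomainError(ValueError):
    """A model or simulation parameter is outside its valid domain."""


class DegenerateInputError(ValueError):
    """Input data are structurally valid but carry no usable information."""


class ConfigurationError(ValueError):
    """Inconsistent simulation or pipeline configuration."""


class InvalidPlateError(ValueError):
    """A microdilution plate fails its control sanity checks."""


class InsufficientDataError(ValueError):
    """Too few observations for the requested computation."""


@dataclass
class PhotonTrace:
    """Binned photon counts for one detector run.

    Parameters
    ----------
    run_kind:
        One of ``"DL"``, ``"SPE"``, ``"background"``.
    counts:
        Non-negative integer counts, one per bin.
    bin_width:
        Bin width in seconds (1 s per detection point by default).
    sample_id:
        Identifier of the leaf sample the run belongs to ("" for
        instrument-only background runs).
    """

    run_kind: str
    counts: np.ndarray
    bin_width: float = 1.0
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.run_kind not in RUN_KINDS:
            raise ValueError(f"run_kind must be one of {RUN_KINDS}, got {self.run_kind!r}")
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or counts.size == 0:
            raise DegenerateInputError("counts must be a non-empty 1-D sequence")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        self.counts = counts
        if self.bin_width <= 0:
            raise ParameterDomainError("bin_width must be positive")

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def duration(self) -> float:
        """Total run length in seconds (n_bins x bin_width)."""
        return self.n_bins * self.bin_width

    @property
    def rates(self) -> np.ndarray:
        """Per-bin count rates in counts/s."""
        return self.counts / self.bin_width

    def mean_rate(self) -> float:
        """Average count rate over the whole run (counts/s)."""
        return float(self.counts.sum() / self.duration)


@dataclass
class SampleRecord:
    """Per-sample metadata: identity, treatment group and physical size.

    mass (g) and thickness (mm) feed the intensity normalization; the
    stress-time index orders repeated measurement days within a group.
    """

    sample_id: str
    group: str
    mass: float
    thickness: float
    stress_time: int = 0

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ParameterDomainError("mass must be positive (g)")
        if self.thickness <= 0:
            raise ParameterDomainError("thickness must be positive (mm)")
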