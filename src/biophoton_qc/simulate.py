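"""Synthetic study generator: photon traces, sample metadata and assay tables.

Emulates a stress-physiology study on *Isatis indigotica* leaves: groups of
leaves (control, three salinity levels, drought) are measured on a
photon-counting detector (delayed-luminescence decays, spontaneous-emission
runs, dark-count background), then assayed for active-compound contents,
photosynthetic pigments, electrolyte leakage, mitochondrial ROS production
and antibacterial activity (broth-microdilution MIC).

Counting noise is Poisson throughout: each bin's count is drawn from a
Poisson law whose mean is the exact integral of the decay law over the bin
plus the dark-count contribution.  Stress acts on the decay curve by
scaling the intensity parameter A (halving the initial intensity I0 under
severe stress) while leaving the time constants B and C — and hence the
decay time T — unchanged; assay endpoints are scaled per group so that the
canonical correlation structure (emission intensity positively tied to
pigments and compound contents, negatively to electrolyte leakage, ROS and
MIC) is present in the generated data.

Every trace and table draws from its own pseudo-random stream derived from
(seed, sample id, run kind), so generation is reproducible and
order-independent.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .bioassay import dilution_ladder
from .core import (
    BACKGROUND_BINS,
    DL_DURATION,
    SPE_BINS,
    ConfigurationError,
    ParameterDomainError,
    PhotonTrace,
    SampleRecord,
)
from .photonics import gu_bin_means

__all__ = [
    "COMPOUNDS",
    "GroupEffect",
    "SimulationConfig",
    "Experiment",
    "default_config",
    "simulate_dl_trace",
    "simulate_spe_trace",
    "simulate_assay_tables",
    "simulate_feature_table",
    "simulate_experiment",
]

#: the five quantified active compounds (columns of the content table, % w/w)
COMPOUNDS = ("hydroxyquinazoline", "syringic_acid", "tryptanthrin", "indigo", "indirubin")

ORGANISMS = ("e_coli", "s_aureus")


def _stream(seed: int, *keys: str) -> np.random.Generator:
    """Independent generator for (seed, keys): stable across generation order."""
    entropy = [int(seed) & 0x7FFFFFFF] + [zlib.crc32(k.encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass
class GroupEffect:
    """Multiplicative effects of one treatment group relative to control.

    ``dl_A`` scales the decay-law intensity parameter A (and hence I0 and
    Iw, leaving B, C and T untouched); ``compounds`` holds per-analyte
    content multipliers; ``mic_shift`` counts two-fold ladder steps the MIC
    moves up from the control value, per organism.
    """

    dl_A: float = 1.0
    spe_rate: float | None = None  # absolute counts/s; None = keep config default
    compounds: dict = field(default_factory=dict)
    pigment: float = 1.0
    rec: float = 1.0
    ros: float = 1.0
    mic_shift: dict = field(default_factory=dict)


@dataclass
class SimulationConfig:
    """Full parameterization of one synthetic study."""

    seed: int = 0
    n_per_group: int = 6
    groups: tuple = ("control", "salt_low", "salt_mid", "salt_high", "drought")
    # control decay-curve truth (counts/s scale, s, dimensionless)
    dl_params_per_group: dict = field(default_factory=dict)
    spe_rate_per_group: dict = field(default_factory=dict)
    background_rate: float = 30.0
    mass_mean: float = 0.5
    mass_sd: float = 0.05
    thickness_mean: float = 0.4
    thickness_sd: float = 0.05
    effect_table: dict = field(default_factory=dict)
    n_dl_replicates: int = 3
    dl_duration: float = DL_DURATION
    spe_bins: int = SPE_BINS
    background_bins: int = BACKGROUND_BINS
    bin_width: float = 1.0
    # control assay baselines
    compound_baseline: dict = field(default_factory=lambda: {
        "hydroxyquinazoline": 0.05, "syringic_acid": 0.08,
        "tryptanthrin": 0.15, "indigo": 0.20, "indirubin": 0.10,
    })
    pigment_baseline: dict = field(default_factory=lambda: {
        "A474": 0.6, "A642": 0.4, "A665": 0.8,
    })
    rec_baseline: float = 0.18
    ros_k1_baseline: float = 0.30   # intensity/s, sample-tube slope
    ros_k2: float = 0.05            # intensity/s, blank-tube slope
    mic_control: dict = field(default_factory=lambda: {"e_coli": 128.0, "s_aureus": 128.0})
    mic_ladder_top: float = 1024.0
    mic_wells: int = 8
    mic_replicates: int = 4
    mic_jitter_prob: float = 0.05   # per-replicate chance of a one-step upward call
    assay_cv: float = 0.08          # lognormal coefficient of variation on endpoints

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ConfigurationError("n_per_group must be at least 2")
        for name, table in (("dl_params_per_group", self.dl_params_per_group),
                            ("spe_rate_per_group", self.spe_rate_per_group),
                            ("effect_table", self.effect_table)):
            missing = set(self.groups) - set(table)
            if missing:
                raise ConfigurationError(f"{name} missing groups: {sorted(missing)}")
        for g, (A, B, C) in self.dl_params_per_group.items():
            if A <= 0 or B <= 0 or C <= 0:
                raise ConfigurationError(f"group {g!r}: A, B, C must all be positive")
        for g, r in self.spe_rate_per_group.items():
            if r < 0:
                raise ConfigurationError(f"group {g!r}: SPE rate must be non-negative")
        if self.background_rate < 0:
            raise ConfigurationError("background_rate must be non-negative")


def default_config(seed: int = 0, n_per_group: int = 6) -> SimulationConfig:
    """Study conditions used throughout: six replicate runs per group, a
    control decay curve with I0 ~ 5.5e3 counts/s, severe stress halving I0,
    and assay effects graded with stress severity.
    """
    control_dl = (1500.0, 10.0, 0.5)
    a_mult = {"control": 1.0, "salt_low": 0.95, "salt_mid": 0.75,
              "salt_high": 0.5, "drought": 0.5}
    spe = {"control": 80.0, "salt_low": 75.0, "salt_mid": 60.0,
           "salt_high": 40.0, "drought": 40.0}
    comp_mult = {
        "control":   {c: 1.0 for c in COMPOUNDS},
        "salt_low":  {"hydroxyquinazoline": 1.0, "syringic_acid": 0.95,
                      "tryptanthrin": 0.95, "indigo": 0.95, "indirubin": 0.95},
        "salt_mid":  {"hydroxyquinazoline": 0.95, "syringic_acid": 0.70,
                      "tryptanthrin": 0.65, "indigo": 0.60, "indirubin": 0.60},
        "salt_high": {"hydroxyquinazoline": 0.85, "syringic_acid": 0.35,
                      "tryptanthrin": 0.25, "indigo": 0.22, "indirubin": 0.18},
        "drought":   {"hydroxyquinazoline": 0.80, "syringic_acid": 0.55,
                      "tryptanthrin": 0.50, "indigo": 0.50, "indirubin": 0.46},
    }
    pig = {"control": 1.0, "salt_low": 0.9, "salt_mid": 0.7, "salt_high": 0.5, "drought": 0.6}
    rec = {"control": 1.0, "salt_low": 1.2, "salt_mid": 2.36, "salt_high": 3.0, "drought": 2.68}
    ros = {"control": 1.0, "salt_low": 1.2, "salt_mid": 1.8, "salt_high": 2.5, "drought": 2.2}
    mic = {"control": {"e_coli": 0, "s_aureus": 0},
           "salt_low": {"e_coli": 0, "s_aureus": 0},
           "salt_mid": {"e_coli": 1, "s_aureus": 1},
           "salt_high": {"e_coli": 2, "s_aureus": 2},
           "drought": {"e_coli": 2, "s_aureus": 3}}
    groups = ("control", "salt_low", "salt_mid", "salt_high", "drought")
    cfg = SimulationConfig(
        seed=seed,
        n_per_group=n_per_group,
        groups=groups,
        dl_params_per_group={g: (control_dl[0] * a_mult[g], control_dl[1], control_dl[2])
                             for g in groups},
        spe_rate_per_group=spe,
        effect_table={g: GroupEffect(dl_A=a_mult[g], compounds=comp_mult[g],
                                     pigment=pig[g], rec=rec[g], ros=ros[g],
                                     mic_shift=mic[g])
                      for g in groups},
    )
    cfg.validate()
    return cfg


def simulate_dl_trace(
    A: float,
    B: float,
    C: float,
    background_rate: float = 0.0,
    duration: float = DL_DURATION,
    bin_width: float = 1.0,
    seed: int = 0,
    sample_id: str = "",
    rng: np.random.Generator | None = None,
) -> PhotonTrace:
    """Poisson delayed-luminescence decay trace.

    Each bin's count is Poisson with mean equal to the exact integral of
    A*csch^2(t/B + C) over the bin plus background_rate * bin_width; the
    time origin t = 0 is the first detection instant after illumination
    ends, with half-open [k, k+1) s bins.
    """
    if A < 0:
        raise ParameterDomainError("intensity parameter A must be non-negative")
    if B <= 0 or C <= 0:
        raise ParameterDomainError("B and C must be positive (model diverges at t=0 for C<=0)")
    if background_rate < 0:
        raise ParameterDomainError("background_rate must be non-negative")
    if duration <= 0 or bin_width <= 0:
        raise ParameterDomainError("duration and bin_width must be positive")
    n_bins = int(round(duration / bin_width))
    edges = np.arange(n_bins + 1, dtype=float) * bin_width
    means = gu_bin_means(edges, A, B, C) + background_rate * bin_width
    if rng is None:
        rng = _stream(seed, sample_id, "DL")
    counts = rng.poisson(means)
    return PhotonTrace(run_kind="DL", counts=counts, bin_width=bin_width, sample_id=sample_id)


def simulate_spe_trace(
    rate: float,
    background_rate: float = 0.0,
    n_bins: int = SPE_BINS,
    bin_width: float = 1.0,
    seed: int = 0,
    sample_id: str = "",
    run_kind: str = "SPE",
    rng: np.random.Generator | None = None,
) -> PhotonTrace:
    """Steady-state trace: i.i.d. Poisson counts with mean
    (rate + background_rate) * bin_width.  Also used with ``rate=0`` and
    ``run_kind="background"`` for instrument dark-count runs.
    """
    if rate < 0 or background_rate < 0:
        raise ParameterDomainError("rates must be non-negative")
    if n_bins < 1:
        raise ParameterDomainError("need at least one bin")
    if rng is None:
        rng = _stream(seed, sample_id, run_kind)
    counts = rng.poisson((rate + background_rate) * bin_width, size=int(n_bins))
    return PhotonTrace(run_kind=run_kind, counts=counts, bin_width=bin_width,
                       sample_id=sample_id)


def _lognoise(rng: np.random.Generator, cv: float, size=None):
    """Mean-one multiplicative lognormal noise with coefficient of variation cv."""
    sigma = np.sqrt(np.log1p(cv ** 2))
    return rng.lognormal(-sigma ** 2 / 2.0, sigma, size=size)


def _sample_ids(config: SimulationConfig) -> list[tuple[str, str]]:
    return [(f"{g}-{i + 1}", g) for g in config.groups for i in range(config.n_per_group)]


def simulate_assay_tables(config: SimulationConfig) -> dict[str, pd.DataFrame]:
    """Generate all wet-lab assay tables for one study.

    Returns a dict of tidy data frames keyed ``compounds`` (five analyte
    contents, % w/w), ``pigments`` (absorbances at 474/642/665 nm with
    extract volume and weighed mass), ``conductivity`` (E1 <= E2 <= E3,
    uS/cm), ``ros_fluorescence`` (per-tube fluorescence-vs-time points) and
    ``mic_plates`` (per-well OD600 readings on the two-fold ladder).
    Group effects are applied multiplicatively so the configured
    correlation signs between photon parameters and endpoints are present.
    """
    config.validate()
    seed = config.seed
    cv = config.assay_cv
    ids = _sample_ids(config)

    comp_rows, pig_rows, cond_rows, ros_rows = [], [], [], []
    for sid, g in ids:
        eff: GroupEffect = config.effect_table[g]
        rng = _stream(seed, sid, "assay")
        row = {"sample_id": sid, "group": g}
        for c in COMPOUNDS:
            mult = eff.compounds.get(c, 1.0)
            row[c] = config.compound_baseline[c] * mult * _lognoise(rng, cv)
        comp_rows.append(row)

        pig = {"sample_id": sid, "group": g, "extract_volume_l": 0.015, "mass_g": 0.1}
        for band, base in config.pigment_baseline.items():
            pig[band] = max(base * eff.pigment * _lognoise(rng, cv), 0.0)
        pig_rows.append(pig)

        e1 = 2.0 + rng.normal(0.0, 0.05)
        e3 = 60.0 * _lognoise(rng, 0.03)
        rec_true = min(config.rec_baseline * eff.rec * _lognoise(rng, cv), 0.95)
        cond_rows.append({"sample_id": sid, "group": g,
                          "E1": e1, "E2": e1 + rec_true * (e3 - e1), "E3": e3})

        k1 = config.ros_k2 + (config.ros_k1_baseline - config.ros_k2) * eff.ros * _lognoise(rng, cv)
        times = np.arange(0.0, 600.0, 60.0)
        for tube, slope in (("sample", k1), ("blank", config.ros_k2)):
            fl = 100.0 + slope * times + rng.normal(0.0, 2.0, size=times.size)
            for t, f in zip(times, fl):
                ros_rows.append({"sample_id": sid, "group": g, "tube": tube,
                                 "time_s": t, "fluorescence": f, "mass_g": 0.1})

    mic_rows = []
    ladder = dilution_ladder(config.mic_ladder_top, config.mic_wells)
    for g in config.groups:
        eff = config.effect_table[g]
        for org in ORGANISMS:
            base_mic = config.mic_control[org] * 2.0 ** eff.mic_shift.get(org, 0)
            for rep in range(1, config.mic_replicates + 1):
                rng = _stream(seed, f"{g}:{org}:{rep}", "mic")
                mic_true = base_mic * (2.0 if rng.random() < config.mic_jitter_prob else 1.0)
                for conc in ladder:
                    od = (rng.normal(0.06, 0.01) if conc >= mic_true
                          else rng.normal(0.65, 0.03))
                    mic_rows.append({"group": g, "organism": org, "replicate": rep,
                                     "role": "drug", "concentration": conc,
                                     "od600": max(od, 0.0)})
                mic_rows.append({"group": g, "organism": org, "replicate": rep,
                                 "role": "positive", "concentration": np.nan,
                                 "od600": max(rng.normal(0.70, 0.02), 0.0)})
                mic_rows.append({"group": g, "organism": org, "replicate": rep,
                                 "role": "negative", "concentration": np.nan,
                                 "od600": max(rng.normal(0.04, 0.005), 0.0)})

    return {
        "compounds": pd.DataFrame(comp_rows),
        "pigments": pd.DataFrame(pig_rows),
        "conductivity": pd.DataFrame(cond_rows),
        "ros_fluorescence": pd.DataFrame(ros_rows),
        "mic_plates": pd.DataFrame(mic_rows),
    }


def simulate_feature_table(
    n_per_group: int = 6,
    groups: tuple = ("control", "stress"),
    effect_columns: tuple = ("I0", "CPS"),
    effect_size: float = 4.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Feature table with a group effect planted in selected columns only.

    All seven candidate parameters (A, B, C, I0, Iw, T, CPS) are standard
    normal noise; rows of every non-control group are shifted by
    ``effect_size`` (in SD units) in ``effect_columns``.  The default of
    4 SD mirrors the separation severe stress produces in the full
    generator: normalized I0 halves while its within-group relative spread
    is ~15%, i.e. a shift of roughly four within-group SDs.  Used for
    screening-recovery studies where the signal carrier must be known
    exactly.
    """
    cols = ("A", "B", "C", "I0", "Iw", "T", "CPS")
    unknown = set(effect_columns) - set(cols)
    if unknown:
        raise ConfigurationError(f"unknown effect columns: {sorted(unknown)}")
    rng = _stream(seed, "feature_table")
    rows = []
    for g in groups:
        X = rng.normal(size=(n_per_group, len(cols)))
        df = pd.DataFrame(X, columns=cols)
        if g != groups[0]:
            for c in effect_columns:
                df[c] += effect_size
        df.insert(0, "group", g)
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    out.insert(0, "sample_id", [f"{g}-{i}" for g in groups for i in range(n_per_group)])
    return out


@dataclass
class Experiment:
    """One fully generated study: metadata, traces and assay tables."""

    config: SimulationConfig
    samples: list
    traces: dict          # sample_id -> {"dl": [PhotonTrace...], "spe": ..., "background": ...}
    assays: dict          # table name -> DataFrame

    @property
    def samples_df(self) -> pd.DataFrame:
        return pd.DataFrame([{"sample_id": s.sample_id, "group": s.group,
                              "mass_g": s.mass, "thickness_mm": s.thickness,
                              "stress_time": s.stress_time} for s in self.samples])


def simulate_experiment(config: SimulationConfig | None = None) -> Experiment:
    """Generate metadata, all photon traces and all assay tables for a study.

    Per sample: ``n_dl_replicates`` DL decay runs, one SPE run and one
    background run, each from its own (seed, sample, run)-derived stream.
    """
    if config is None:
        config = default_config()
    config.validate()
    seed = config.seed

    samples = []
    traces: dict = {}
    for sid, g in _sample_ids(config):
        meta_rng = _stream(seed, sid, "meta")
        mass = max(meta_rng.normal(config.mass_mean, config.mass_sd), config.mass_mean * 0.2)
        thick = max(meta_rng.normal(config.thickness_mean, config.thickness_sd),
                    config.thickness_mean * 0.2)
        samples.append(SampleRecord(sample_id=sid, group=g, mass=mass, thickness=thick))

        A, B, C = config.dl_params_per_group[g]
        dl = [
            simulate_dl_trace(
                A, B, C, background_rate=config.background_rate,
                duration=config.dl_duration, bin_width=config.bin_width,
                rng=_stream(seed, sid, f"DL:{r}"), sample_id=sid,
            )
            for r in range(config.n_dl_replicates)
        ]
        spe = simulate_spe_trace(
            config.spe_rate_per_group[g], config.background_rate,
            n_bins=config.spe_bins, bin_width=config.bin_width,
            rng=_stream(seed, sid, "SPE"), sample_id=sid,
        )
        bg = simulate_spe_trace(
            0.0, config.background_rate,
            n_bins=config.background_bins, bin_width=config.bin_width,
            rng=_stream(seed, sid, "background"), sample_id=sid, run_kind="background",
        )
        traces[sid] = {"dl": dl, "spe": spe, "background": bg}

    assays = simulate_assay_tables(config)
    return Experiment(config=config, samples=samples, traces=traces, assays=assays)
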