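"""End-to-end orchestration, on-disk formats and the run manifest.

Stage order mirrors the bench workflow: (optional) simulation -> decay-model
fitting and CPS -> physiological indices -> MIC calling -> LASSO screening,
PCA and t-tests -> correlation networks -> quality classification ->
report.  All tabular outputs are comma-separated UTF-8 with a header row;
the network is additionally exported as GraphML.  A JSON manifest records
the configuration snapshot, the seed, stage provenance and a SHA-256 hash
of every output file, so a re-run with the same manifest reproduces
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bioassay import MicPlate, call_mic, summarize_mic
from .core import PhotonTrace, SampleRecord
from .photonics import (
    compute_cps,
    derive_dl_parameters,
    fit_gu_model,
    normalize_intensity,
    summarize_replicate_fits,
)
from .physiology import PigmentAssay, RECAssay, ROSAssay, pigment_contents, \
    relative_conductivity, ros_rate
from .screening import (
    classify_quality,
    group_ttest,
    lasso_screen,
    pca_stratify,
    spearman_network,
)
from .simulate import Experiment, SimulationConfig, default_config, simulate_experiment

__all__ = [
    "RunManifest",
    "write_trace_csv",
    "read_trace_csv",
    "build_feature_table",
    "physiology_table",
    "mic_tables",
    "endpoint_table",
    "run_pipeline",
]

STRESS_ARMS = {
    "salt": ("control", "salt_low", "salt_mid", "salt_high"),
    "drought": ("control", "drought"),
}


# ---------------------------------------------------------------------------
# Formats


def write_trace_csv(trace: PhotonTrace, path) -> None:
    """Trace CSV: columns time_s (bin start) and counts."""
    t = np.arange(trace.n_bins) * trace.bin_width
    pd.DataFrame({"time_s": t, "counts": trace.counts}).to_csv(path, index=False)


def read_trace_csv(path, run_kind: str, sample_id: str = "") -> PhotonTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    bin_width = float(t[1] - t[0]) if t.size > 1 else 1.0
    return PhotonTrace(run_kind=run_kind, counts=df["counts"].to_numpy(),
                       bin_width=bin_width, sample_id=sample_id)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    seed: int
    config: dict
    version: str = __version__
    created: str = ""
    stages: list = field(default_factory=list)
    outputs: dict = field(default_factory=dict)   # relative path -> sha256
    warnings: list = field(default_factory=list)

    def register(self, out_dir: Path, path: Path) -> None:
        self.outputs[str(path.relative_to(out_dir))] = _sha256(path)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# Stage: photon parameters


def build_feature_table(
    experiment: Experiment,
    m: float = 3.0,
    W: float | None = None,
    weighting: str = "poisson",
) -> pd.DataFrame:
    """Fit every sample's DL replicates, derive I0/T/Iw, compute CPS, and
    assemble the per-sample candidate-parameter table.

    Replicates are fitted independently and averaged; the strength
    indicators I0, Iw and CPS are geometry-normalized (x thickness / mass)
    into the columns the screening stage consumes, with raw values kept
    alongside.
    """
    W = W if W is not None else experiment.config.dl_duration
    rows = []
    for sample in experiment.samples:
        runs = experiment.traces[sample.sample_id]
        bg_rate = runs["background"].mean_rate()
        fits = [fit_gu_model(tr, background_rate=bg_rate, weighting=weighting)
                for tr in runs["dl"]]
        fit = summarize_replicate_fits(fits)
        derived = derive_dl_parameters(fit, m=m, W=W)
        spe = compute_cps(runs["spe"], runs["background"])
        rows.append({
            "sample_id": sample.sample_id,
            "group": sample.group,
            "mass_g": sample.mass,
            "thickness_mm": sample.thickness,
            "A": fit.A, "B": fit.B, "C": fit.C,
            "A_sd": fit.A_sd, "B_sd": fit.B_sd, "C_sd": fit.C_sd,
            "n_replicates": fit.n_replicates,
            "I0_raw": derived.I0, "Iw_raw": derived.Iw, "T": derived.T,
            "CPS_raw": spe.cps,
            "I0": normalize_intensity(derived.I0, sample),
            "Iw": normalize_intensity(derived.Iw, sample),
            "CPS": normalize_intensity(spe.cps, sample),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Stage: physiology


def physiology_table(assays: dict) -> pd.DataFrame:
    """Per-sample physiological indices from the raw assay tables."""
    pig = assays["pigments"]
    cond = assays["conductivity"]
    ros = assays["ros_fluorescence"]
    rows = []
    for _, r in pig.iterrows():
        contents = pigment_contents(PigmentAssay(
            A474=r["A474"], A642=r["A642"], A665=r["A665"],
            V=r.get("extract_volume_l", 0.015), mass=r.get("mass_g", 0.1)))
        rows.append({"sample_id": r["sample_id"], "group": r["group"],
                     "total_chlorophyll": contents.total_chlorophyll,
                     "carotenoid": contents.carotenoid,
                     "total_pigment": contents.total_pigment})
    out = pd.DataFrame(rows).set_index("sample_id")

    rec = {r["sample_id"]: relative_conductivity(RECAssay(r["E1"], r["E2"], r["E3"]))
           for _, r in cond.iterrows()}
    out["REC"] = pd.Series(rec)

    ros_vals = {}
    for sid, sub in ros.groupby("sample_id"):
        sample_pts = sub[sub["tube"] == "sample"][["time_s", "fluorescence"]].to_numpy()
        blank_pts = sub[sub["tube"] == "blank"][["time_s", "fluorescence"]].to_numpy()
        g = float(sub["mass_g"].iloc[0])
        ros_vals[sid] = ros_rate(ROSAssay(sample_pts, blank_pts, g))
    out["ROS"] = pd.Series(ros_vals)
    return out.reset_index()


# ---------------------------------------------------------------------------
# Stage: MIC


def mic_tables(mic_plates: pd.DataFrame, endpoint_fraction: float = 0.8):
    """Call every replicate plate and summarize per group and organism."""
    calls, summaries = [], []
    for (g, org, rep), sub in mic_plates.groupby(["group", "organism", "replicate"]):
        drug = sub[sub["role"] == "drug"].sort_values("concentration", ascending=False)
        plate = MicPlate(
            concentrations=drug["concentration"].to_numpy(),
            od_wells=drug["od600"].to_numpy(),
            od_positive=float(sub.loc[sub["role"] == "positive", "od600"].iloc[0]),
            od_negative=float(sub.loc[sub["role"] == "negative", "od600"].iloc[0]),
            organism=org, replicate=int(rep),
        )
        mic = call_mic(plate, endpoint_fraction=endpoint_fraction)
        calls.append({"group": g, "organism": org, "replicate": int(rep),
                      "mic": mic.value, "qualifier": mic.qualifier})
    calls_df = pd.DataFrame(calls)
    for (g, org), sub in calls_df.groupby(["group", "organism"]):
        s = summarize_mic(list(sub["mic"]))
        summaries.append({"group": g, "organism": org, "consensus": s.consensus,
                          "low": s.low, "high": s.high, "n": s.n})
    return calls_df, pd.DataFrame(summaries)


# ---------------------------------------------------------------------------
# Stage: endpoints for correlation


def endpoint_table(assays: dict, physiology: pd.DataFrame,
                   mic_summary: pd.DataFrame) -> pd.DataFrame:
    """Per-sample endpoint matrix: compound contents, pigment contents,
    REC, ROS rate and the group-consensus MIC per organism."""
    comp = assays["compounds"].set_index("sample_id")
    out = comp.drop(columns=["group"]).join(
        physiology.set_index("sample_id").drop(columns=["group"]))
    mic_wide = mic_summary.pivot(index="group", columns="organism", values="consensus")
    mic_wide.columns = [f"MIC_{o}" for o in mic_wide.columns]
    out = out.join(comp["group"].map(mic_wide.to_dict(orient="index")).apply(pd.Series))
    out.insert(0, "group", comp["group"])
    return out.reset_index()


# ---------------------------------------------------------------------------
# Full pipeline


def run_pipeline(
    config: SimulationConfig | None = None,
    out_dir: str | Path = "pipeline_out",
    seed: int | None = None,
    correlation_threshold: float = 0.05,
    quality_threshold: float = 0.02,
) -> RunManifest:
    """Run every stage on a (simulated) study and write all outputs.

    Returns the :class:`RunManifest`; all randomness flows from the single
    configuration seed, so repeated runs are byte-identical.
    """
    if config is None:
        config = default_config(seed=seed if seed is not None else 0)
    elif seed is not None:
        config = dataclasses.replace(config, seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=config.seed, config=_config_dict(config),
                           created=datetime.now(timezone.utc).isoformat())

    def save(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False, float_format="%.10g")
        manifest.register(out, path)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        experiment = simulate_experiment(config)
        save(experiment.samples_df, "samples.csv")
        for name, df in experiment.assays.items():
            save(df, f"assay_{name}.csv")
        manifest.stages.append("simulate")

        features = build_feature_table(experiment)
        save(features, "features.csv")
        manifest.stages.append("photonics")

        physiology = physiology_table(experiment.assays)
        save(physiology, "physiology.csv")
        manifest.stages.append("physiology")

        mic_calls, mic_summary = mic_tables(experiment.assays["mic_plates"])
        save(mic_calls, "mic_calls.csv")
        save(mic_summary, "mic_summary.csv")
        manifest.stages.append("mic")

        # screening: control vs any-stress membership
        response = (features["group"] != "control").astype(int)
        screen = lasso_screen(features, response,
                              feature_columns=("A", "B", "C", "I0", "Iw", "T", "CPS"),
                              seed=config.seed)
        screen_json = {
            "lambda_path": screen.lambda_path.tolist(),
            "cv_mean": screen.cv_mean.tolist(),
            "cv_se": screen.cv_se.tolist(),
            "lambda_min": screen.lambda_min,
            "lambda_1se": screen.lambda_1se,
            "selected_min": screen.selected_min,
            "selected_1se": screen.selected_1se,
        }
        spath = out / "screening.json"
        spath.write_text(json.dumps(screen_json, indent=2))
        manifest.register(out, spath)

        scores, explained = pca_stratify(features, ("I0", "CPS"))
        scores["explained_pc1"] = explained[0]
        save(scores, "pca_scores.csv")

        trows = []
        ctrl = features[features["group"] == "control"]
        for g in config.groups:
            if g == "control":
                continue
            sub = features[features["group"] == g]
            for param in ("I0", "CPS", "T"):
                res = group_ttest(ctrl[param], sub[param])
                trows.append({"group": g, "parameter": param, "t": res.t,
                              "df": res.df, "p": res.p, "significant": res.significant})
        save(pd.DataFrame(trows), "ttests.csv")
        manifest.stages.append("screen")

        endpoints = endpoint_table(experiment.assays, physiology, mic_summary)
        params = features.set_index("sample_id")[["I0", "CPS", "T"]]
        all_edges = []
        for arm, arm_groups in STRESS_ARMS.items():
            present = [g for g in arm_groups if g in config.groups]
            if len(present) < 2:
                continue
            sids = features.loc[features["group"].isin(present), "sample_id"]
            ep = endpoints[endpoints["sample_id"].isin(sids)].set_index("sample_id")
            net = spearman_network(params.loc[sids], ep.drop(columns=["group"]),
                                   threshold=correlation_threshold)
            net.to_graphml(out / f"network_{arm}.graphml")
            manifest.register(out, out / f"network_{arm}.graphml")
            edges = net.edges.copy()
            edges.insert(0, "arm", arm)
            all_edges.append(edges)
        save(pd.concat(all_edges, ignore_index=True), "network_edges.csv")
        manifest.stages.append("correlate")

        quality = classify_quality(experiment.assays["compounds"],
                                   threshold=quality_threshold)
        save(quality, "quality.csv")
        manifest.stages.append("quality")

        manifest.warnings = sorted({str(w.message) for w in caught})

    manifest.write(out / "manifest.json")
    return manifest


def _config_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    # tuples/np types -> JSON-safe
    return json.loads(json.dumps(d, default=lambda o: list(o) if hasattr(o, "__iter__") else str(o)))
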