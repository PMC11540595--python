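"""Orchestration: configuration, seeding, delimited I/O and the full pipeline.

Stages (simulate -> respond -> bcn -> decode -> modelfit) run off one global
seed; every stage derives its own seed by hashing (global_seed, stage_name),
and each run writes a manifest (config hash, seeds, versions) alongside its
tables so exact stages are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import reference
from .bilateral import bootstrap_bcn_null
from .decoding import build_pseudopopulation, decode_odor, decode_side
from .hemimodel import METRIC_NAMES, ModelConfig, compute_alignment_metrics, fit_alpha, \
    simulate_bilateral_cortices
from .responses import ResponseMatrix, build_response_matrix, matrix_to_frame, \
    summarize_population
from .synthdata import BLANK, SIDES, GlomerularPanel, SessionRecording, \
    generate_glomerular_panel, generate_ground_truth_tuning, generate_session_design, \
    generate_trials

logger = logging.getLogger("olfbilat")

__all__ = [
    "RunConfig",
    "derive_seed",
    "run_pipeline",
    "read_session",
    "write_session",
    "read_matrix",
    "write_matrix",
    "read_panel",
    "write_panel",
]

SESSION_COLUMNS = ["neuron_id", "stimulus_id", "side", "repetition",
                   "count_before", "count_during", "window_before_s", "window_during_s"]
MATRIX_COLUMNS = ["neuron_id", "odor_id", "side", "R_hz", "p_value", "significant"]


def derive_seed(global_seed: int, stage: str, rep: int = 0) -> int:
    """Deterministic per-stage seed below 2**31 from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}:{rep}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class RunConfig:
    """Parameters for every pipeline stage plus the global seed.

    ``region`` presets set the sparseness and baseline constants measured in
    each cortical area (AON: sparseness 0.224/0.252, baseline 3.9 Hz;
    APC: baseline 2.8 Hz); every field remains overridable.
    """

    seed: int = 0
    region: str = "AON"
    n_neurons: int = 300
    n_odors: int = 15
    n_sides: int = 2
    n_reps: int = 7
    p_respond: float = reference.AON_SPARSENESS_IPSI
    bcn_fraction: float = 0.3
    slope: float = 0.75
    baseline_median_hz: float = reference.AON_BASELINE_HZ
    magnitude_scale_hz: float = 3.5
    positive_fraction: float = reference.AON_POSITIVE_FRACTION
    blank_delta_hz: float = 0.0
    n_glomeruli: int = 155
    similarity_target: float = 0.3
    bootstrap_iter: int = 2000
    decode_repeats: int = 200
    decode_neurons: int | None = None
    model_neurons: int = 5000
    model_gamma: float = 3.5
    model_xi: float = 0.5
    alpha_grid: list[float] = field(default_factory=lambda: [round(0.05 * k, 2)
                                                             for k in range(21)])
    model_sample: int = 385
    model_sample_reps: int = 50
    sparseness_ipsi: float = reference.AON_SPARSENESS_IPSI
    sparseness_contra: float = reference.AON_SPARSENESS_CONTRA

    def __post_init__(self) -> None:
        if self.region not in ("AON", "APC"):
            raise ValueError("region preset must be AON or APC")
        if self.region == "APC" and self.baseline_median_hz == reference.AON_BASELINE_HZ:
            self.baseline_median_hz = reference.APC_BASELINE_HZ

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# delimited I/O
# ---------------------------------------------------------------------------


def write_session(recording: SessionRecording, path: str | Path) -> None:
    """One row per (neuron, trial): lossless delimited round trip."""
    n, t = recording.counts_before.shape
    trials = recording.trials
    frame = pd.DataFrame({
        "neuron_id": np.repeat(recording.neuron_ids, t),
        "stimulus_id": np.tile(trials["stimulus"].to_numpy(), n),
        "side": np.tile(trials["side"].to_numpy(), n),
        "repetition": np.tile(trials["repetition"].to_numpy(), n),
        "count_before": recording.counts_before.ravel(),
        "count_during": recording.counts_during.ravel(),
        "window_before_s": recording.window_before_s,
        "window_during_s": recording.window_during_s,
    })
    frame.to_csv(path, sep="\t", index=False)


def _validated_read(path: str | Path, columns: list[str]) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return frame


def read_session(path: str | Path, require_blanks: bool = False) -> SessionRecording:
    """Parse a session table; malformed rows fail with their line number."""
    frame = _validated_read(path, SESSION_COLUMNS)
    for col in ("count_before", "count_during"):
        vals = pd.to_numeric(frame[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals != vals.round())
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise ValueError(f"{path}: malformed {col} at line {line}")
    bad_side = ~frame["side"].isin(SIDES)
    if bad_side.any():
        raise ValueError(f"{path}: unknown side at line {int(bad_side.idxmax()) + 2}")

    neuron_ids = list(dict.fromkeys(frame["neuron_id"]))
    first = frame[frame["neuron_id"] == neuron_ids[0]]
    trials = first[["stimulus_id", "side", "repetition"]].rename(
        columns={"stimulus_id": "stimulus"}).reset_index(drop=True)
    t = len(trials)
    if len(frame) != t * len(neuron_ids):
        raise ValueError(f"{path}: every neuron must have the same trial set")
    before = frame["count_before"].to_numpy().reshape(len(neuron_ids), t).astype(int)
    during = frame["count_during"].to_numpy().reshape(len(neuron_ids), t).astype(int)
    rec = SessionRecording(
        neuron_ids=neuron_ids, trials=trials, counts_before=before, counts_during=during,
        window_before_s=float(frame["window_before_s"].iloc[0]),
        window_during_s=float(frame["window_during_s"].iloc[0]),
    )
    if rec.n_reps < 2:
        raise ValueError(f"{path}: at least 2 repetitions required")
    if require_blanks:
        for side in rec.sides:
            if not rec.trial_mask(BLANK, side).any():
                raise ValueError(f"{path}: blank trials missing on side {side!r}")
    return rec


def write_matrix(matrix: ResponseMatrix, path: str | Path) -> None:
    matrix_to_frame(matrix).to_csv(path, sep="\t", index=False)


def read_matrix(path: str | Path) -> ResponseMatrix:
    frame = _validated_read(path, MATRIX_COLUMNS)
    neuron_ids = list(dict.fromkeys(frame["neuron_id"]))
    odors = sorted(frame["odor_id"].unique())
    sides = [s for s in SIDES if s in set(frame["side"])]
    shape = (len(neuron_ids), len(odors), len(sides))
    R = np.full(shape, np.nan)
    p = np.full(shape, np.nan)
    sig = np.zeros(shape, dtype=bool)
    ni = {v: i for i, v in enumerate(neuron_ids)}
    oi = {v: i for i, v in enumerate(odors)}
    si = {v: i for i, v in enumerate(sides)}
    for row in frame.itertuples(index=False):
        i, o, s = ni[row.neuron_id], oi[row.odor_id], si[row.side]
        R[i, o, s] = row.R_hz
        p[i, o, s] = row.p_value
        sig[i, o, s] = bool(row.significant)
    if np.isnan(R).any():
        raise ValueError(f"{path}: incomplete neuron x odor x side grid")
    return ResponseMatrix(R=R, p=p, significant=sig, n_reps=0,
                          neuron_ids=neuron_ids, odors=odors, sides=sides)


def write_panel(panel: GlomerularPanel, path: str | Path) -> None:
    frame = pd.DataFrame(panel.x, index=panel.odors,
                         columns=[f"glom{j:03d}" for j in range(panel.n_glomeruli)])
    frame.to_csv(path, sep="\t", index_label="odor")


def read_panel(path: str | Path) -> GlomerularPanel:
    frame = pd.read_csv(path, sep="\t", index_col="odor")
    return GlomerularPanel(frame.to_numpy(), odors=list(frame.index))


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def _stage(name: str, t0: float, **info) -> None:
    logger.info("stage=%s elapsed=%.2fs %s", name, time.perf_counter() - t0,
                " ".join(f"{k}={v}" for k, v in info.items()))


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """simulate -> respond -> bcn -> decode -> modelfit, with a manifest.

    Each stage writes a delimited table (or JSON summary) under ``outdir``;
    reruns with an identical config are bit-identical for the exact stages.
    Any stage failure aborts with the stage name attached.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "seeds": {},
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "outputs": [],
    }
    results: dict = {}

    def run_stage(name, fn):
        t0 = time.perf_counter()
        manifest["seeds"][name] = derive_seed(config.seed, name)
        try:
            fn(manifest["seeds"][name])
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        _stage(name, t0)

    state: dict = {}

    def simulate(seed):
        panel = generate_glomerular_panel(config.n_glomeruli, config.n_odors,
                                          config.similarity_target, seed=seed)
        schedule = generate_session_design(config.n_odors, config.n_sides, config.n_reps,
                                           seed=derive_seed(config.seed, "schedule"))
        tuning = generate_ground_truth_tuning(
            config.n_neurons, p_respond=config.p_respond, bcn_fraction=config.bcn_fraction,
            slope=config.slope, baseline_median_hz=config.baseline_median_hz,
            magnitude_scale_hz=config.magnitude_scale_hz,
            positive_fraction=config.positive_fraction, n_odors=config.n_odors,
            blank_delta_hz=config.blank_delta_hz, seed=derive_seed(config.seed, "tuning"),
        )
        recording = generate_trials(tuning, schedule, seed=derive_seed(config.seed, "trials"))
        write_panel(panel, out / "panel.tsv")
        write_session(recording, out / "session.tsv")
        state.update(panel=panel, tuning=tuning, recording=recording)
        manifest["outputs"] += ["panel.tsv", "session.tsv"]

    def respond(seed):
        matrix = build_response_matrix(state["recording"])
        write_matrix(matrix, out / "responses.tsv")
        summary = summarize_population(matrix)
        results["sparseness"] = summary.sparseness.tolist()
        state["matrix"] = matrix
        manifest["outputs"].append("responses.tsv")

    def bcn(seed):
        boot = bootstrap_bcn_null(state["matrix"], n_iter=config.bootstrap_iter, seed=seed)
        results["bcn_fraction"] = boot.fraction_observed
        results["bcn_p_bootstrap"] = boot.p_bootstrap
        state["bcn_flags"] = boot.bcn_flags
        pd.DataFrame({"null_fraction": boot.null_fractions}).to_csv(
            out / "bcn_null.tsv", sep="\t", index=False)
        manifest["outputs"].append("bcn_null.tsv")

    def decode(seed):
        pop = build_pseudopopulation(state["recording"], region=config.region,
                                     bcn_flags=state["bcn_flags"])
        rows = []
        for train, test in (("ipsi", "ipsi"), ("ipsi", "contra"),
                            ("contra", "contra"), ("contra", "ipsi")):
            r = decode_odor(pop, train, test, n_neurons=config.decode_neurons,
                            n_repeats=config.decode_repeats, seed=seed)
            rows.append(("odor", train, test, r.accuracy_mean, r.accuracy_sd, r.chance))
        r = decode_side(pop, n_neurons=config.decode_neurons,
                        n_repeats=config.decode_repeats, seed=seed)
        rows.append(("side", "both", "both", r.accuracy_mean, r.accuracy_sd, r.chance))
        frame = pd.DataFrame(rows, columns=["task", "train_side", "test_side",
                                            "accuracy", "sd", "chance"])
        frame.to_csv(out / "decoding.tsv", sep="\t", index=False)
        results["decoding"] = frame.to_dict("records")
        manifest["outputs"].append("decoding.tsv")

    def modelfit(seed):
        mcfg = ModelConfig(n_neurons=config.model_neurons, n_glomeruli=config.n_glomeruli,
                           n_odors=config.n_odors, gamma=config.model_gamma,
                           sparseness_ipsi=config.sparseness_ipsi,
                           sparseness_contra=config.sparseness_contra,
                           xi=config.model_xi, seed=seed)
        n_sample = min(config.model_sample, config.model_neurons)
        ipsi, contra = simulate_bilateral_cortices(state["panel"], mcfg, seed=seed)
        data = compute_alignment_metrics(ipsi, contra, n_sample=n_sample,
                                         n_reps=config.model_sample_reps,
                                         seed=derive_seed(config.seed, "modelfit-data"))
        fit = fit_alpha(data.as_array(), state["panel"], mcfg,
                        alpha_grid=np.asarray(config.alpha_grid),
                        seed=derive_seed(config.seed, "modelfit-scan"),
                        n_sample=n_sample, n_reps=config.model_sample_reps)
        rows = [
            dict(alpha=float(a), z2=float(z),
                 **{k: getattr(m, k) for k in METRIC_NAMES})
            for a, z, m in zip(fit.alpha_grid, fit.z2, fit.metrics_by_alpha)
        ]
        pd.DataFrame(rows).to_csv(out / "model_alpha_scan.tsv", sep="\t", index=False)
        results["alpha_star"] = fit.alpha_star
        results["data_metrics"] = {k: getattr(data, k) for k in METRIC_NAMES}
        with open(out / "model_fit.json", "w") as fh:
            json.dump({"alpha_star": fit.alpha_star,
                       "data_metrics": results["data_metrics"]}, fh, indent=2)
        manifest["outputs"] += ["model_alpha_scan.tsv", "model_fit.json"]

    for name, fn in (("simulate", simulate), ("respond", respond), ("bcn", bcn),
                     ("decode", decode), ("modelfit", modelfit)):
        run_stage(name, fn)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return results
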