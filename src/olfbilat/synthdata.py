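"""Synthetic bilateral odor-session generator.

Emulates the study design used for bilateral olfactory-cortex recordings:
15 monomolecular odors plus a solvent-only "blank", each delivered to the
ipsilateral or contralateral nostril and repeated 7 times (224 presentations
per session), with spike counts collected in a 4 s pre-stimulus window and a
2 s response window.  Ground-truth tuning is sparse and signed, a controllable
fraction of neurons carries matched ipsi/contra tuning (the bilaterally
correlated neurons, BCNs), and trial noise is Poisson on window counts.

Everything is seeded and deterministic; the generator is the test bed for the
response, BCN, decoding and model-fitting stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import erfcinv

SIDES = ("ipsi", "contra")
BLANK = "blank"

__all__ = [
    "SIDES",
    "BLANK",
    "GlomerularPanel",
    "TrialSchedule",
    "GroundTruthTuning",
    "SessionRecording",
    "generate_glomerular_panel",
    "generate_session_design",
    "generate_ground_truth_tuning",
    "generate_trials",
    "odor_names",
]


def odor_names(n_odors: int) -> list[str]:
    """Canonical stimulus identifiers ``odor01`` ... ``odorNN``."""
    return [f"odor{k + 1:02d}" for k in range(n_odors)]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GlomerularPanel:
    """Odor x glomerulus response matrix with equalized per-odor norms.

    ``x`` holds nonnegative response amplitudes (dF/F-like units), one row per
    odor; ``cos_theta`` the pairwise cosine similarities between odor rows.
    Because rows are nonnegative, similarities lie in [0, 1].
    """

    x: np.ndarray
    odors: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim != 2:
            raise ValueError("panel matrix must be 2-D (odors x glomeruli)")
        if np.any(self.x < 0):
            raise ValueError("glomerular responses must be nonnegative")
        if not self.odors:
            self.odors = odor_names(self.x.shape[0])

    @property
    def n_odors(self) -> int:
        return self.x.shape[0]

    @property
    def n_glomeruli(self) -> int:
        return self.x.shape[1]

    @property
    def cos_theta(self) -> np.ndarray:
        norms = np.linalg.norm(self.x, axis=1, keepdims=True)
        unit = self.x / norms
        c = unit @ unit.T
        return np.clip(c, 0.0, 1.0)


@dataclass
class TrialSchedule:
    """Seeded permutation of the full factorial (stimuli x sides x reps) design."""

    entries: pd.DataFrame  # columns: stimulus, side, repetition
    odor_duration_s: float = 2.0
    inter_trial_s: float = 15.0

    @property
    def n_trials(self) -> int:
        return len(self.entries)

    @property
    def stimuli(self) -> list[str]:
        return sorted(self.entries["stimulus"].unique())

    @property
    def odors(self) -> list[str]:
        return [s for s in self.stimuli if s != BLANK]

    @property
    def sides(self) -> list[str]:
        return [s for s in SIDES if s in set(self.entries["side"])]

    @property
    def n_reps(self) -> int:
        return int(self.entries["repetition"].max()) + 1


@dataclass
class GroundTruthTuning:
    """Latent rates behind a synthetic session.

    ``delta_hz[i, o, s]`` is neuron *i*'s signed firing-rate perturbation to
    odor *o* on side *s* (0 = ipsi, 1 = contra), relative to baseline-plus-blank.
    ``bcn_flag`` marks neurons whose contralateral tuning was generated as
    ``slope_true * ipsi + noise`` rather than independently.
    """

    baseline_hz: np.ndarray  # (n_neurons,)
    delta_hz: np.ndarray  # (n_neurons, n_odors, 2)
    blank_delta_hz: np.ndarray  # (n_neurons, 2)
    bcn_flag: np.ndarray  # (n_neurons,) bool
    slope_true: float
    odors: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(self.baseline_hz < 0):
            raise ValueError("baselines must be nonnegative")
        if not self.odors:
            self.odors = odor_names(self.delta_hz.shape[1])

    @property
    def n_neurons(self) -> int:
        return self.baseline_hz.shape[0]

    @property
    def n_odors(self) -> int:
        return self.delta_hz.shape[1]


@dataclass
class SessionRecording:
    """Trial-resolved spike counts for one synthetic session.

    ``counts_before``/``counts_during`` are (n_neurons, n_trials) integer
    arrays; ``trials`` carries stimulus, side and repetition per trial.
    """

    neuron_ids: list[str]
    trials: pd.DataFrame  # columns: stimulus, side, repetition
    counts_before: np.ndarray
    counts_during: np.ndarray
    window_before_s: float = 4.0
    window_during_s: float = 2.0

    def __post_init__(self) -> None:
        if self.counts_before.shape != self.counts_during.shape:
            raise ValueError("count arrays must share a shape")
        if self.counts_before.shape != (len(self.neuron_ids), len(self.trials)):
            raise ValueError("count arrays must be (n_neurons, n_trials)")
        for arr in (self.counts_before, self.counts_during):
            if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
                raise ValueError("counts must be nonnegative integers")

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_ids)

    @property
    def odors(self) -> list[str]:
        return sorted(s for s in self.trials["stimulus"].unique() if s != BLANK)

    @property
    def sides(self) -> list[str]:
        return [s for s in SIDES if s in set(self.trials["side"])]

    @property
    def n_reps(self) -> int:
        return int(self.trials["repetition"].max()) + 1

    def trial_mask(self, stimulus: str, side: str) -> np.ndarray:
        m = (self.trials["stimulus"] == stimulus) & (self.trials["side"] == side)
        return m.to_numpy()

    def counts_for(self, stimulus: str, side: str) -> tuple[np.ndarray, np.ndarray]:
        """(before, during) counts ordered by repetition index, shape (n_neurons, n_reps)."""
        mask = self.trial_mask(stimulus, side)
        idx = np.flatnonzero(mask)
        order = np.argsort(self.trials["repetition"].to_numpy()[idx], kind="stable")
        idx = idx[order]
        return self.counts_before[:, idx], self.counts_during[:, idx]


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def generate_glomerular_panel(
    n_glomeruli: int,
    n_odors: int,
    similarity_target: float | np.ndarray = 0.3,
    seed: int = 0,
    noise_sparsity: float = 0.1,
    tol: float = 0.02,
) -> GlomerularPanel:
    """Nonnegative odor x glomerulus panel with a target mean cosine similarity.

    Each odor row is ``w * shared + private`` where ``shared`` is a common
    nonnegative profile and ``private`` is sparse half-normal noise
    (``noise_sparsity`` fraction of glomeruli per odor); the shared weight *w*
    is bisected until the realized mean off-diagonal cosine similarity is
    within ``tol`` of the target.  Rows are then divisively normalized to a
    common Euclidean norm.

    A matrix ``similarity_target`` is reduced to its off-diagonal mean (the
    contract is on the mean similarity, not individual entries).
    """
    if n_glomeruli < n_odors:
        raise ValueError("need at least as many glomeruli as odors")
    target = np.asarray(similarity_target, dtype=float)
    if target.ndim == 2:
        off = ~np.eye(target.shape[0], dtype=bool)
        target = float(target[off].mean())
    else:
        target = float(target)
    if not 0.0 <= target < 1.0:
        raise ValueError("similarity target must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    shared = np.abs(rng.standard_normal(n_glomeruli))
    mask = rng.random((n_odors, n_glomeruli)) < noise_sparsity
    private = np.abs(rng.standard_normal((n_odors, n_glomeruli))) * mask
    # guard against all-zero rows at low sparsity
    dead = private.sum(axis=1) == 0
    if np.any(dead):
        private[dead, rng.integers(0, n_glomeruli, size=int(dead.sum()))] = 1.0

    def mean_offdiag(w: float) -> float:
        panel = GlomerularPanel(w * shared[None, :] + private, odors=odor_names(n_odors))
        if n_odors == 1:
            return 0.0
        c = panel.cos_theta
        return float(c[~np.eye(n_odors, dtype=bool)].mean())

    floor = mean_offdiag(0.0)
    if target < floor - 0.05:
        raise ValueError(
            f"mean off-diagonal similarity {target:.3f} unreachable: the sparse "
            f"nonnegative construction cannot go below {floor:.3f}"
        )
    lo, hi = 0.0, 1.0
    while mean_offdiag(hi) < target and hi < 1e6:
        hi *= 2.0
    w = 0.0
    if target > floor:
        for _ in range(60):
            w = 0.5 * (lo + hi)
            if mean_offdiag(w) < target:
                lo = w
            else:
                hi = w
            if hi - lo < 1e-9 * max(1.0, hi):
                break
        w = 0.5 * (lo + hi)

    x = w * shared[None, :] + private
    x = x / np.linalg.norm(x, axis=1, keepdims=True)  # divisive normalization
    return GlomerularPanel(x, odors=odor_names(n_odors))


def generate_session_design(
    n_odors: int = 15,
    n_sides: int = 2,
    n_reps: int = 7,
    odor_duration_s: float = 2.0,
    inter_trial_s: float = 15.0,
    seed: int = 0,
) -> TrialSchedule:
    """Shuffled full factorial design: (odors + blank) x sides x repetitions."""
    if min(n_odors, n_sides, n_reps) < 1:
        raise ValueError("all design counts must be >= 1")
    if n_sides > 2:
        raise ValueError("at most two sides (ipsi, contra)")
    stimuli = odor_names(n_odors) + [BLANK]
    rows = [
        (stim, side, rep)
        for stim in stimuli
        for side in SIDES[:n_sides]
        for rep in range(n_reps)
    ]
    frame = pd.DataFrame(rows, columns=["stimulus", "side", "repetition"])
    rng = np.random.default_rng(seed)
    frame = frame.iloc[rng.permutation(len(frame))].reset_index(drop=True)
    return TrialSchedule(frame, odor_duration_s=odor_duration_s, inter_trial_s=inter_trial_s)


def _tail_magnitudes(rng, size, p_respond: float, scale: float, dist: str) -> np.ndarray:
    """Response magnitudes; default is the thresholded-Gaussian tail implied by
    the cortical model (excess of |N(0, scale^2)| over the threshold matching
    sparseness ``p_respond``)."""
    if dist == "gaussian_tail":
        rho = math.sqrt(2.0) * float(erfcinv(p_respond)) if 0 < p_respond < 1 else 0.0
        z = stats.truncnorm.rvs(rho, np.inf, size=size, random_state=rng)
        return scale * (z - rho)
    if dist == "exponential":
        return rng.exponential(scale, size=size)
    raise ValueError(f"unknown magnitude distribution {dist!r}")


def generate_ground_truth_tuning(
    n_neurons: int,
    p_respond: float = 0.224,
    bcn_fraction: float = 0.3,
    slope: float = 0.75,
    baseline_median_hz: float = 3.9,
    magnitude_scale_hz: float = 3.5,
    positive_fraction: float = 0.46,
    n_odors: int = 15,
    coupling_noise_hz: float = 0.3,
    blank_delta_hz: float = 0.0,
    magnitude_dist: str = "gaussian_tail",
    baseline_spread: float = 0.6,
    seed: int = 0,
) -> GroundTruthTuning:
    """Sparse, signed, optionally bilaterally matched ground-truth tuning.

    Ipsilateral tuning: each (neuron, odor) pair responds with probability
    ``p_respond``; magnitudes follow the Gaussian-tail law at scale
    ``magnitude_scale_hz``; each neuron's response sign is drawn once
    (``positive_fraction`` of neurons are all-excitatory), reproducing the
    bimodal positive-negative balance seen in cortical recordings.

    A ``bcn_fraction`` subset of neurons copies its ipsilateral tuning to the
    contralateral side through ``slope`` plus Gaussian coupling noise; the
    rest draw contralateral tuning independently, which leaves their expected
    ipsi/contra correlation at zero.

    Baselines are log-normal with median ``baseline_median_hz``.
    """
    for name, p in (("p_respond", p_respond), ("bcn_fraction", bcn_fraction),
                    ("positive_fraction", positive_fraction)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if baseline_median_hz <= 0 or magnitude_scale_hz <= 0:
        raise ValueError("rates must be positive")

    rng = np.random.default_rng(seed)
    baseline = baseline_median_hz * np.exp(baseline_spread * rng.standard_normal(n_neurons))
    sign = np.where(rng.random(n_neurons) < positive_fraction, 1.0, -1.0)
    bcn = rng.random(n_neurons) < bcn_fraction

    delta = np.zeros((n_neurons, n_odors, 2))

    def draw_side() -> np.ndarray:
        mask = rng.random((n_neurons, n_odors)) < p_respond
        mags = np.zeros((n_neurons, n_odors))
        k = int(mask.sum())
        if k:
            mags[mask] = _tail_magnitudes(rng, k, p_respond, magnitude_scale_hz, magnitude_dist)
        return sign[:, None] * mags

    ipsi = draw_side()
    contra_indep = draw_side()
    noise = coupling_noise_hz * rng.standard_normal((n_neurons, n_odors))
    contra_coupled = slope * ipsi + np.where(ipsi != 0, noise, 0.0)
    delta[:, :, 0] = ipsi
    delta[:, :, 1] = np.where(bcn[:, None], contra_coupled, contra_indep)

    blank = np.full((n_neurons, 2), float(blank_delta_hz))
    return GroundTruthTuning(
        baseline_hz=baseline,
        delta_hz=delta,
        blank_delta_hz=blank,
        bcn_flag=bcn,
        slope_true=slope,
        odors=odor_names(n_odors),
    )


def generate_trials(
    tuning: GroundTruthTuning,
    schedule: TrialSchedule,
    seed: int = 0,
    window_before_s: float = 4.0,
    window_during_s: float = 2.0,
) -> SessionRecording:
    """Poisson spike counts for every (neuron, trial) in the schedule.

    Before-window counts are Poisson(baseline * window_before); during-window
    counts are Poisson(clip(baseline + delta, 0) * window_during), where delta
    is the odor/side perturbation (blank trials use the blank perturbation).
    """
    missing = set(schedule.odors) - set(tuning.odors)
    if missing:
        raise ValueError(f"schedule references odors absent from tuning: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    odor_index = {o: k for k, o in enumerate(tuning.odors)}
    side_index = {s: k for k, s in enumerate(SIDES)}

    n, t = tuning.n_neurons, schedule.n_trials
    during_rate = np.empty((n, t))
    stim = schedule.entries["stimulus"].to_numpy()
    side = schedule.entries["side"].to_numpy()
    for j in range(t):
        s = side_index[side[j]]
        if stim[j] == BLANK:
            d = tuning.blank_delta_hz[:, s]
        else:
            d = tuning.delta_hz[:, odor_index[stim[j]], s]
        during_rate[:, j] = tuning.baseline_hz + d
    np.clip(during_rate, 0.0, None, out=during_rate)

    before = rng.poisson(tuning.baseline_hz[:, None] * window_before_s, size=(n, t))
    during = rng.poisson(during_rate * window_during_s)
    return SessionRecording(
        neuron_ids=[f"n{k:04d}" for k in range(n)],
        trials=schedule.entries.copy(),
        counts_before=before,
        counts_during=during,
        window_before_s=window_before_s,
        window_during_s=window_during_s,
    )
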