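"""Blank-subtracted trial-averaged responses and their significance.

The response of a neuron to an odor *o* on one side is

    R = mean_t(Dur_o^t - Bef_o^t) - mean_t(Dur_b^t - Bef_b^t)   [Hz]

where Dur/Bef are firing rates in the 2 s response and 4 s pre-stimulus
windows and *b* indexes the paired blank (solvent-only) trials.  Significance
of each (neuron, odor, side) pair is a two-sided Wilcoxon signed-rank test of
the per-trial odor deltas against the paired blank deltas at the 5% level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthdata import BLANK, SessionRecording

__all__ = [
    "SignificanceResult",
    "ResponseMatrix",
    "PopulationSummary",
    "compute_response",
    "test_response_significance",
    "build_response_matrix",
    "summarize_population",
]

CRITICAL_P = 0.05  # the study-wide critical value


@dataclass
class SignificanceResult:
    p_value: float
    degenerate: bool = False

    def __float__(self) -> float:
        return self.p_value


@dataclass
class ResponseMatrix:
    """Mean responses R (Hz) with per-pair Wilcoxon p-values.

    Arrays are (n_neurons, n_odors, n_sides); ``sides`` is ordered
    (ipsi, contra).  ``p`` and ``significant`` are NaN/False when p-values
    were not computed (``compute_pvalues=False``).
    """

    R: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    n_reps: int
    neuron_ids: list[str]
    odors: list[str]
    sides: list[str]
    degenerate: np.ndarray | None = None

    @property
    def n_neurons(self) -> int:
        return self.R.shape[0]

    @property
    def n_odors(self) -> int:
        return self.R.shape[1]

    def side_index(self, side: str) -> int:
        return self.sides.index(side)


@dataclass
class PopulationSummary:
    """Per-neuron tuning summaries (number of significant odors, magnitudes,
    positive-negative balance) and per-side sparseness."""

    n_odors_significant: np.ndarray  # (n_neurons, n_sides)
    magnitudes: list[np.ndarray]  # per side, |R| over significant pairs
    balance: np.ndarray  # (n_neurons, n_sides), NaN when undefined
    sparseness: np.ndarray  # (n_sides,)
    sides: list[str] = field(default_factory=list)


def compute_response(
    during_odor: np.ndarray,
    before_odor: np.ndarray,
    during_blank: np.ndarray,
    before_blank: np.ndarray,
) -> float:
    """Blank-subtracted mean response (Hz) from per-trial firing rates."""
    arrs = [np.asarray(a, dtype=float) for a in
            (during_odor, before_odor, during_blank, before_blank)]
    n = arrs[0].shape[-1]
    if any(a.shape[-1] != n for a in arrs):
        raise ValueError("odor and blank trials must have equal counts")
    d_o, b_o, d_b, b_b = arrs
    return float(np.mean(d_o - b_o) - np.mean(d_b - b_b))


_SIGN_CACHE: dict[int, np.ndarray] = {}
_EXACT_LIMIT = 14  # enumerate 2^m sign assignments up to this many nonzero pairs


def _sign_matrix(m: int) -> np.ndarray:
    if m not in _SIGN_CACHE:
        bits = np.arange(2**m)[:, None] >> np.arange(m)[None, :]
        _SIGN_CACHE[m] = (bits & 1).astype(float)
    return _SIGN_CACHE[m]


def _signed_rank_p(diff: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p for one vector of paired differences.

    Zero differences are dropped; tied magnitudes get midranks.  Up to 14
    remaining pairs the exact conditional null (all 2^m sign assignments of
    the observed ranks) is enumerated — with no ties this reproduces the
    classic exact distribution; beyond that a normal approximation with
    continuity correction is used (midranks tie-correct the variance
    sum(r^2)/4).
    """
    d = diff[diff != 0]
    m = d.size
    if m == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if m <= _EXACT_LIMIT:
        null = _sign_matrix(m) @ ranks
        p = 2.0 * min(float((null <= w + 1e-9).mean()), float((null >= w - 1e-9).mean()))
        return min(1.0, p)
    mean = ranks.sum() / 2.0
    sd = float(np.sqrt((ranks**2).sum() / 4.0))
    z = (abs(w - mean) - 0.5) / sd
    return min(1.0, 2.0 * float(stats.norm.sf(z)))


def test_response_significance(
    odor_deltas: np.ndarray, blank_deltas: np.ndarray
) -> SignificanceResult:
    """Two-sided Wilcoxon signed-rank p of paired (odor - blank) rate deltas.

    Pairs are matched by repetition index.  Zero differences are dropped
    (classic Wilcoxon handling); if every difference is zero the test is
    degenerate and p = 1 is returned with a flag.  The null distribution is
    exact (sign-assignment enumeration) at the study's n = 7.
    """
    x = np.asarray(odor_deltas, dtype=float)
    y = np.asarray(blank_deltas, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    diff = x - y
    if np.all(diff == 0):
        return SignificanceResult(1.0, degenerate=True)
    return SignificanceResult(_signed_rank_p(diff), degenerate=False)


def _rate_deltas(rec: SessionRecording, stimulus: str, side: str,
                 window_during_s: float) -> np.ndarray:
    """Per-repetition (during - before) rates, shape (n_neurons, n_reps)."""
    before, during = rec.counts_for(stimulus, side)
    return during / window_during_s - before / rec.window_before_s


def build_response_matrix(
    recording: SessionRecording,
    window_during_s: float | None = None,
    blank_subtract: bool = True,
    compute_pvalues: bool = True,
    alpha: float = CRITICAL_P,
) -> ResponseMatrix:
    """Apply the response statistic and significance test per (neuron, odor, side).

    With ``blank_subtract`` off, R = mean_t(Dur_o - Bef_o) (the robustness
    variant); the significance test is then against zero deltas.
    """
    win = recording.window_during_s if window_during_s is None else window_during_s
    odors, sides = recording.odors, recording.sides
    n, p, s = recording.n_neurons, len(odors), len(sides)
    if blank_subtract:
        for side in sides:
            if not recording.trial_mask(BLANK, side).any():
                raise ValueError(f"blank subtraction requested but no blank trials on {side!r}")

    R = np.zeros((n, p, s))
    pvals = np.full((n, p, s), np.nan)
    degen = np.zeros((n, p, s), dtype=bool)
    for si, side in enumerate(sides):
        if blank_subtract:
            blank_d = _rate_deltas(recording, BLANK, side, win)
        else:
            blank_d = None
        for oi, odor in enumerate(odors):
            odor_d = _rate_deltas(recording, odor, side, win)
            ref = blank_d if blank_d is not None else np.zeros_like(odor_d)
            if odor_d.shape[1] != ref.shape[1]:
                raise ValueError("odor and blank repetition counts differ")
            R[:, oi, si] = (odor_d - ref).mean(axis=1)
            if compute_pvalues:
                for i in range(n):
                    res = test_response_significance(odor_d[i], ref[i])
                    pvals[i, oi, si] = res.p_value
                    degen[i, oi, si] = res.degenerate
    sig = np.where(np.isnan(pvals), False, pvals < alpha)
    return ResponseMatrix(
        R=R, p=pvals, significant=sig.astype(bool), n_reps=recording.n_reps,
        neuron_ids=list(recording.neuron_ids), odors=odors, sides=sides,
        degenerate=degen,
    )


def summarize_population(matrix: ResponseMatrix) -> PopulationSummary:
    """Counts, significant-magnitude distributions, positive-negative balance
    and per-side sparseness (fraction of significant neuron-odor pairs)."""
    sig = matrix.significant
    n_sig = sig.sum(axis=1)  # (n_neurons, n_sides)
    n_pos = (sig & (matrix.R > 0)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        balance = np.where(n_sig > 0, n_pos / np.maximum(n_sig, 1), np.nan)
    mags = [np.abs(matrix.R[:, :, si][sig[:, :, si]]) for si in range(sig.shape[2])]
    sparseness = sig.mean(axis=(0, 1))
    return PopulationSummary(
        n_odors_significant=n_sig,
        magnitudes=mags,
        balance=balance,
        sparseness=sparseness,
        sides=list(matrix.sides),
    )


def matrix_to_frame(matrix: ResponseMatrix) -> pd.DataFrame:
    """Long-format table: neuron_id, odor_id, side, R_hz, p_value, significant."""
    rows = []
    for i, nid in enumerate(matrix.neuron_ids):
        for oi, odor in enumerate(matrix.odors):
            for si, side in enumerate(matrix.sides):
                rows.append((nid, odor, side, matrix.R[i, oi, si],
                             matrix.p[i, oi, si], bool(matrix.significant[i, oi, si])))
    return pd.DataFrame(rows, columns=["neuron_id", "odor_id", "side", "R_hz",
                                       "p_value", "significant"])
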