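"""Bilaterally correlated neurons (BCNs) and their resampling nulls.

A neuron is bilaterally correlated when the ordinary least-squares regression
of its per-odor contralateral responses on its ipsilateral responses
(contra = a * ipsi + b, over the 15 odors) is significant by F test at 5%.
This module detects BCNs, builds the odor-shuffle bootstrap null for their
prevalence, estimates the trial-noise ceiling with Poisson surrogates, the
split-half (3/4 of 7 trials) upper bound, and runs the per-odor population
regressions with a neuron-identity shuffle null.

All per-neuron regressions run through one vectorized closed-form OLS + F-test
helper; it is cross-checked against scipy.stats.linregress in the tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .responses import CRITICAL_P, ResponseMatrix
from .synthdata import BLANK, SessionRecording

__all__ = [
    "RegressionResult",
    "BcnSummary",
    "ols_f_test",
    "regress_bilateral",
    "identify_bcns",
    "bootstrap_bcn_null",
    "poisson_correlation_ceiling",
    "split_half_bcn",
    "population_regression_per_odor",
]


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_points: int
    degenerate: bool = False


@dataclass
class BcnSummary:
    bcn_flags: np.ndarray  # per analyzed neuron
    fraction_observed: float
    null_fractions: np.ndarray | None = None
    p_bootstrap: float | None = None
    subset_mask: np.ndarray | None = None


def ols_f_test(x: np.ndarray, y: np.ndarray):
    """Vectorized simple OLS of y on x along the last axis.

    Returns (slope, intercept, r_squared, p_value, valid) where the F test is
    for a nonzero slope (1 and n-2 df; equivalent to the two-sided t test).
    ``valid`` is False for constant x or n < 3; such fits are degenerate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[-1]
    xm = x.mean(axis=-1, keepdims=True)
    ym = y.mean(axis=-1, keepdims=True)
    sxx = ((x - xm) ** 2).sum(axis=-1)
    syy = ((y - ym) ** 2).sum(axis=-1)
    sxy = ((x - xm) * (y - ym)).sum(axis=-1)
    valid = (sxx > 0) & (n >= 3)
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        slope = np.where(valid, sxy / np.where(sxx > 0, sxx, 1.0), np.nan)
        intercept = ym[..., 0] - slope * xm[..., 0]
        r2 = np.where(valid & (syy > 0), sxy**2 / np.where((sxx * syy) > 0, sxx * syy, 1.0), 0.0)
        r2 = np.clip(r2, 0.0, 1.0)
        f = r2 * (n - 2) / np.maximum(1.0 - r2, np.finfo(float).tiny)
        p = np.where(valid, stats.f.sf(f, 1, n - 2), np.nan)
    return slope, intercept, r2, p, valid


def regress_bilateral(ipsi: np.ndarray, contra: np.ndarray) -> RegressionResult:
    """OLS of contralateral on ipsilateral per-odor responses with F-test p."""
    ipsi = np.asarray(ipsi, dtype=float)
    contra = np.asarray(contra, dtype=float)
    if ipsi.shape != contra.shape or ipsi.ndim != 1:
        raise ValueError("ipsi and contra must be 1-D vectors of equal length")
    if ipsi.size < 3:
        raise ValueError("need at least 3 odors for a regression")
    slope, intercept, r2, p, valid = ols_f_test(ipsi, contra)
    if not valid:
        return RegressionResult(np.nan, np.nan, np.nan, np.nan, ipsi.size, degenerate=True)
    return RegressionResult(float(slope), float(intercept), float(r2), float(p), ipsi.size)


def _subset_mask(matrix: ResponseMatrix, subset: str) -> np.ndarray:
    sig_any = matrix.significant.any(axis=1)  # (n_neurons, n_sides)
    if subset == "all":
        return np.ones(matrix.n_neurons, dtype=bool)
    if subset == "responsive_one_side":
        return sig_any.any(axis=1)
    if subset == "responsive_both_sides":
        return sig_any.all(axis=1)
    raise ValueError(f"unknown subset {subset!r}")


def _bcn_flags(x: np.ndarray, y: np.ndarray, alpha: float) -> np.ndarray:
    _, _, _, p, valid = ols_f_test(x, y)
    return valid & (p < alpha)


def identify_bcns(
    matrix: ResponseMatrix, subset: str = "all", alpha: float = CRITICAL_P
) -> BcnSummary:
    """Flag BCNs: per-neuron contra~ipsi regression over odors, F test at 5%.

    ``subset`` restricts both numerator and denominator to neurons responding
    significantly to at least one odor on one ("responsive_one_side") or each
    ("responsive_both_sides") side.  Degenerate regressions count as non-BCN.
    """
    if len(matrix.sides) < 2:
        raise ValueError("response matrix must contain both sides")
    mask = _subset_mask(matrix, subset)
    if not mask.any():
        raise ValueError(f"subset {subset!r} selects no neurons")
    ii, ci = matrix.side_index("ipsi"), matrix.side_index("contra")
    flags = _bcn_flags(matrix.R[mask, :, ii], matrix.R[mask, :, ci], alpha)
    return BcnSummary(
        bcn_flags=flags,
        fraction_observed=float(flags.mean()),
        subset_mask=mask,
    )


def bootstrap_bcn_null(
    matrix: ResponseMatrix,
    n_iter: int = 10_000,
    seed: int = 0,
    subset: str = "all",
    alpha: float = CRITICAL_P,
    chunk: int = 256,
) -> BcnSummary:
    """Odor-shuffle bootstrap for the BCN fraction.

    Per iteration, odor identities are independently permuted within each side
    for every neuron before re-running the per-neuron regressions; the
    bootstrap p is (1 + #{null >= observed}) / (1 + n_iter).
    """
    if matrix.n_odors < 2:
        raise ValueError("need at least 2 odors to shuffle")
    if n_iter < 100:
        warnings.warn("fewer than 100 bootstrap iterations: wide confidence interval")
    obs = identify_bcns(matrix, subset=subset, alpha=alpha)
    mask = obs.subset_mask
    ii, ci = matrix.side_index("ipsi"), matrix.side_index("contra")
    x = matrix.R[mask, :, ii]
    y = matrix.R[mask, :, ci]
    n, p = x.shape
    rng = np.random.default_rng(seed)
    fracs = np.empty(n_iter)
    for start in range(0, n_iter, chunk):
        m = min(chunk, n_iter - start)
        perm_x = rng.permuted(np.broadcast_to(np.arange(p), (m, n, p)), axis=-1)
        perm_y = rng.permuted(np.broadcast_to(np.arange(p), (m, n, p)), axis=-1)
        xs = np.take_along_axis(x[None, :, :], perm_x, axis=-1)
        ys = np.take_along_axis(y[None, :, :], perm_y, axis=-1)
        fracs[start:start + m] = _bcn_flags(xs, ys, alpha).mean(axis=-1)
    p_boot = (1.0 + np.sum(fracs >= obs.fraction_observed)) / (1.0 + n_iter)
    return BcnSummary(
        bcn_flags=obs.bcn_flags,
        fraction_observed=obs.fraction_observed,
        null_fractions=fracs,
        p_bootstrap=float(p_boot),
        subset_mask=mask,
    )


def _surrogate_R(rng, mean_before, mean_during, n_reps, win_before, win_during):
    """Blank-subtracted R from Poisson surrogate trials.

    ``mean_*`` are (n_neurons, n_stimuli) mean window counts where the last
    stimulus column is the blank.
    """
    shape = mean_before.shape + (n_reps,)
    before = rng.poisson(mean_before[..., None], size=shape)
    during = rng.poisson(mean_during[..., None], size=shape)
    deltas = during / win_during - before / win_before  # (n, stim, reps)
    blank = deltas[:, -1:, :]
    return (deltas[:, :-1, :] - blank).mean(axis=-1)


def poisson_correlation_ceiling(
    recording: SessionRecording,
    n_iter: int = 100,
    seed: int = 0,
    alpha: float = CRITICAL_P,
) -> np.ndarray:
    """Attainable BCN fraction under pure trial noise.

    Window rates per (neuron, stimulus, side) are estimated from the recording
    (trial-mean counts, hence nonnegative).  Each iteration generates two
    independent sets of 7 artificial Poisson trials and regresses the
    response matrix of set 1 against set 2 of the SAME side; the returned
    array holds the per-iteration fraction of "bilaterally" correlated
    neurons, the ceiling imposed by trial-to-trial variability.
    """
    odors, sides = recording.odors, recording.sides
    n_reps = recording.n_reps
    means = {}
    for side in sides:
        mb = np.empty((recording.n_neurons, len(odors) + 1))
        md = np.empty_like(mb)
        for oi, stim in enumerate(odors + [BLANK]):
            before, during = recording.counts_for(stim, side)
            mb[:, oi] = before.mean(axis=1)
            md[:, oi] = during.mean(axis=1)
        means[side] = (mb, md)
    if all((md.max() == 0) for _, md in means.values()):
        raise ValueError("recording has no nonzero rates")

    rng = np.random.default_rng(seed)
    fracs = np.empty(n_iter)
    for it in range(n_iter):
        flags = []
        for side in sides:
            mb, md = means[side]
            r1 = _surrogate_R(rng, mb, md, n_reps, recording.window_before_s,
                              recording.window_during_s)
            r2 = _surrogate_R(rng, mb, md, n_reps, recording.window_before_s,
                              recording.window_during_s)
            flags.append(_bcn_flags(r1, r2, alpha))
        fracs[it] = np.concatenate(flags).mean()
    return fracs


def split_half_bcn(
    recording: SessionRecording, alpha: float = CRITICAL_P
) -> np.ndarray:
    """Within-side split-half correlation fractions over all trial splits.

    The 7 repetitions are split into every unordered {3, 4} partition
    (C(7,3) = 35 splits); for each split, blank-subtracted responses computed
    from the two trial groups are regressed against each other per neuron and
    side, and the fraction of significant (BCN-style) correlations over all
    (neuron, side) combinations is reported.  Deterministic: no RNG involved.
    """
    n_reps = recording.n_reps
    half = n_reps // 2
    if n_reps != 7:
        warnings.warn(f"{n_reps} repetitions: generalizing to C(n, floor(n/2)) splits")
    odors, sides = recording.odors, recording.sides
    win_b, win_d = recording.window_before_s, recording.window_during_s

    # per-repetition deltas, shape (n_neurons, n_stimuli, n_sides, n_reps)
    deltas = np.empty((recording.n_neurons, len(odors) + 1, len(sides), n_reps))
    for si, side in enumerate(sides):
        for oi, stim in enumerate(odors + [BLANK]):
            before, during = recording.counts_for(stim, side)
            deltas[:, oi, si, :] = during / win_d - before / win_b

    splits = list(combinations(range(n_reps), half))
    fracs = np.empty(len(splits))
    all_reps = set(range(n_reps))
    for k, g1 in enumerate(splits):
        g2 = sorted(all_reps - set(g1))
        flags = []
        for si in range(len(sides)):
            def group_R(reps):
                d = deltas[:, :, si, :][:, :, list(reps)]
                blank = d[:, -1:, :]
                return (d[:, :-1, :] - blank).mean(axis=-1)
            flags.append(_bcn_flags(group_R(g1), group_R(g2), alpha))
        fracs[k] = np.concatenate(flags).mean()
    return fracs


def population_regression_per_odor(
    matrix: ResponseMatrix,
    odor: str,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> tuple[RegressionResult, float]:
    """Across-neuron contra~ipsi regression for one odor with a shuffle null.

    The null permutes neuron identity independently on each side; the shuffle
    p is the smoothed fraction of null |slope| at least as large as observed.
    """
    if matrix.n_neurons < 3:
        raise ValueError("need at least 3 neurons")
    oi = matrix.odors.index(odor)
    ii, ci = matrix.side_index("ipsi"), matrix.side_index("contra")
    x = matrix.R[:, oi, ii]
    y = matrix.R[:, oi, ci]
    result = regress_bilateral(x, y)
    rng = np.random.default_rng(seed)
    perm_x = rng.permuted(np.broadcast_to(x, (n_shuffles, x.size)), axis=-1)
    perm_y = rng.permuted(np.broadcast_to(y, (n_shuffles, y.size)), axis=-1)
    null_slope, _, _, _, valid = ols_f_test(perm_x, perm_y)
    null_slope = np.where(valid, null_slope, 0.0)
    if result.degenerate:
        return result, float("nan")
    p_shuffle = (1.0 + np.sum(np.abs(null_slope) >= abs(result.slope))) / (1.0 + n_shuffles)
    return result, float(p_shuffle)
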