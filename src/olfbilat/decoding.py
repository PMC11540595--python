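"""Nearest-centroid decoding of odor identity and stimulus side.

Features are per-trial during-window spike counts with the mean blank count
(over the 7 blank trials of the same side) subtracted.  Odor decoding holds
out one trial per odor, trains Euclidean centroids on the rest, and assigns
each held-out trial to its nearest centroid; cross-side transfer draws the
test trials from the opposite side.  Side decoding is two-class nearest-mean.
The trial-free centroid-matching decoders used for model comparison live here
too (`match_centroids`, `classify_side_centroid`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthdata import BLANK, SessionRecording

__all__ = [
    "PseudoPopulation",
    "DecodingResult",
    "build_pseudopopulation",
    "decode_odor",
    "decode_side",
    "decode_with_bcn_fraction",
    "match_centroids",
    "classify_side_centroid",
]


@dataclass
class PseudoPopulation:
    """Neurons pooled across recordings with randomly alignable pseudotrials.

    ``features[i, o, s, t]`` is neuron *i*'s blank-subtracted spike count on
    pseudotrial *t* of odor *o*, side *s* (sides ordered ipsi, contra).
    """

    features: np.ndarray  # (n_neurons, n_odors, n_sides, n_trials)
    odors: list[str]
    sides: list[str]
    region: str = ""
    window_s: float = 2.0
    bcn_flags: np.ndarray | None = None

    @property
    def n_neurons(self) -> int:
        return self.features.shape[0]

    @property
    def n_odors(self) -> int:
        return self.features.shape[1]

    @property
    def n_trials(self) -> int:
        return self.features.shape[3]

    def side_index(self, side: str) -> int:
        return self.sides.index(side)


@dataclass
class DecodingResult:
    accuracy_mean: float
    accuracy_sd: float
    n_neurons: int
    n_repeats: int
    train_side: str
    test_side: str
    chance: float
    accuracies: np.ndarray = field(repr=False, default=None)


def _session_features(rec: SessionRecording, blank_subtract: bool) -> np.ndarray:
    odors, sides = rec.odors, rec.sides
    out = np.empty((rec.n_neurons, len(odors), len(sides), rec.n_reps))
    for si, side in enumerate(sides):
        if blank_subtract:
            _, blank_during = rec.counts_for(BLANK, side)
            blank_mean = blank_during.mean(axis=1, keepdims=True)
        else:
            blank_mean = 0.0
        for oi, odor in enumerate(odors):
            _, during = rec.counts_for(odor, side)
            out[:, oi, si, :] = during - blank_mean
    return out


def build_pseudopopulation(
    recordings: SessionRecording | list[SessionRecording],
    region: str = "",
    window_s: float | None = None,
    blank_subtract: bool = True,
    bcn_flags: np.ndarray | None = None,
    seed: int = 0,
) -> PseudoPopulation:
    """Concatenate neurons across recordings into one pseudopopulation.

    All recordings must share the odor panel, sides and repetition count.
    Pseudotrial alignment across neurons is (re-)randomized inside each
    decoding repetition, so the stored trial order is the recorded one.
    """
    if isinstance(recordings, SessionRecording):
        recordings = [recordings]
    ref = recordings[0]
    for rec in recordings[1:]:
        if rec.odors != ref.odors or rec.sides != ref.sides or rec.n_reps != ref.n_reps:
            raise ValueError("recordings must share odor panel, sides and repetitions")
    feats = np.concatenate([_session_features(r, blank_subtract) for r in recordings], axis=0)
    return PseudoPopulation(
        features=feats,
        odors=list(ref.odors),
        sides=list(ref.sides),
        region=region,
        window_s=ref.window_during_s if window_s is None else window_s,
        bcn_flags=None if bcn_flags is None else np.asarray(bcn_flags, dtype=bool),
    )


def _align_pseudotrials(rng, feats: np.ndarray) -> np.ndarray:
    """Independently permute the trial axis per (neuron, odor, side)."""
    n, p, s, t = feats.shape
    perm = rng.permuted(np.broadcast_to(np.arange(t), (n, p, s, t)), axis=-1)
    return np.take_along_axis(feats, perm, axis=-1)


def _nearest(test: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Index of the nearest centroid for each test row (ties -> lowest index)."""
    d2 = ((test[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=-1)
    return d2.argmin(axis=1)


def decode_odor(
    pop: PseudoPopulation,
    train_side: str = "ipsi",
    test_side: str = "ipsi",
    n_neurons: int | None = None,
    n_repeats: int = 200,
    seed: int = 0,
    neuron_pool: np.ndarray | None = None,
) -> DecodingResult:
    """Leave-out nearest-centroid odor decoding, same-side or cross-side.

    Per repeat: subsample neurons, randomly align pseudotrials, hold out one
    trial per odor on the training side, train centroids on the rest, and
    classify the test trials (held-out same-side trials, or one random trial
    per odor from the test side) to the nearest Euclidean centroid.
    """
    pool = np.arange(pop.n_neurons) if neuron_pool is None else np.asarray(neuron_pool)
    n_avail = pool.size
    n_use = n_avail if n_neurons is None else n_neurons
    if n_use > n_avail:
        raise ValueError(f"requested {n_use} neurons but only {n_avail} available")
    if pop.n_trials < 2:
        raise ValueError("need at least 2 trials per odor")
    tr, te = pop.side_index(train_side), pop.side_index(test_side)
    P, T = pop.n_odors, pop.n_trials
    accs = np.empty(n_repeats)
    for rep in range(n_repeats):
        rng = np.random.default_rng((seed, rep))
        idx = pool if n_use == n_avail else rng.choice(pool, n_use, replace=False)
        feats = _align_pseudotrials(rng, pop.features[idx])
        held = rng.integers(0, T, size=P)
        train = feats[:, :, tr, :]
        mask = np.ones((P, T), dtype=bool)
        mask[np.arange(P), held] = False
        centroids = np.stack(
            [train[:, o, mask[o]].mean(axis=1) for o in range(P)], axis=0
        )  # (P, n_use)
        if te == tr:
            test = feats[np.arange(feats.shape[0])[:, None], np.arange(P)[None, :], te,
                         held[None, :]].T  # (P, n_use)
        else:
            pick = rng.integers(0, T, size=P)
            test = feats[:, np.arange(P), te, pick].T
        accs[rep] = float(np.mean(_nearest(test, centroids) == np.arange(P)))
    return DecodingResult(
        accuracy_mean=float(accs.mean()), accuracy_sd=float(accs.std(ddof=0)),
        n_neurons=int(n_use), n_repeats=n_repeats, train_side=train_side,
        test_side=test_side, chance=1.0 / P, accuracies=accs,
    )


def decode_side(
    pop: PseudoPopulation,
    n_neurons: int | None = None,
    n_repeats: int = 200,
    seed: int = 0,
    neuron_pool: np.ndarray | None = None,
) -> DecodingResult:
    """Two-class nearest-mean side (laterality) decoding; chance is 1/2.

    Per repeat, one random odor-trial per side is held out; the remaining
    trials of each side are averaged into a mean side response, and the two
    held-out trials are classified to the nearer mean.  The side mean weights
    odors equally (average of per-odor means) so that holding a trial out
    does not deplete its odor's weight on one side only, which would bias
    classification toward the opposite side.
    """
    if len(pop.sides) < 2:
        raise ValueError("both sides required for side decoding")
    pool = np.arange(pop.n_neurons) if neuron_pool is None else np.asarray(neuron_pool)
    n_use = pool.size if n_neurons is None else n_neurons
    if n_use > pool.size:
        raise ValueError(f"requested {n_use} neurons but only {pool.size} available")
    P, T = pop.n_odors, pop.n_trials
    accs = np.empty(n_repeats)
    for rep in range(n_repeats):
        rng = np.random.default_rng((seed, rep, 1))
        idx = pool if n_use == pool.size else rng.choice(pool, n_use, replace=False)
        feats = _align_pseudotrials(rng, pop.features[idx])
        correct = 0
        tests, means = [], []
        for si in range(2):
            side = feats[:, :, si, :]  # (n, P, T)
            o, t = int(rng.integers(0, P)), int(rng.integers(0, T))
            tests.append(side[:, o, t])
            odor_sums = side.sum(axis=2)  # (n, P)
            odor_means = odor_sums / T
            odor_means[:, o] = (odor_sums[:, o] - side[:, o, t]) / (T - 1)
            means.append(odor_means.mean(axis=1))
        centroids = np.stack(means, axis=0)
        for si in range(2):
            correct += int(_nearest(tests[si][None, :], centroids)[0] == si)
        accs[rep] = correct / 2.0
    return DecodingResult(
        accuracy_mean=float(accs.mean()), accuracy_sd=float(accs.std(ddof=0)),
        n_neurons=int(n_use), n_repeats=n_repeats, train_side="both",
        test_side="both", chance=0.5, accuracies=accs,
    )


def decode_with_bcn_fraction(
    pop: PseudoPopulation,
    n_neurons: int = 135,
    bcn_fraction_grid: list[float] = (0.0, 0.25, 0.5, 0.75, 1.0),
    n_repeats: int = 50,
    seed: int = 0,
    task: str = "odor",
    train_side: str = "ipsi",
    test_side: str = "contra",
) -> list[DecodingResult]:
    """Decoding with a controlled fraction of BCNs among the sampled neurons.

    At each grid point, ``round(f * n_neurons)`` neurons are drawn from the
    BCN-flagged pool and the remainder from the non-BCN pool (stratified,
    without replacement), then odor or side decoding runs as usual.
    """
    if pop.bcn_flags is None:
        raise ValueError("pseudopopulation carries no BCN flags")
    bcn_pool = np.flatnonzero(pop.bcn_flags)
    non_pool = np.flatnonzero(~pop.bcn_flags)
    results = []
    for gi, frac in enumerate(bcn_fraction_grid):
        n_bcn = int(round(frac * n_neurons))
        n_non = n_neurons - n_bcn
        if n_bcn > bcn_pool.size or n_non > non_pool.size:
            raise ValueError(
                f"bcn fraction {frac} infeasible: need {n_bcn} BCN / {n_non} non-BCN, "
                f"have {bcn_pool.size} / {non_pool.size}"
            )
        accs = np.empty(n_repeats)
        for rep in range(n_repeats):
            rng = np.random.default_rng((seed, gi, rep))
            idx = np.concatenate([
                rng.choice(bcn_pool, n_bcn, replace=False),
                rng.choice(non_pool, n_non, replace=False),
            ])
            if task == "odor":
                r = decode_odor(pop, train_side, test_side, n_neurons=n_neurons,
                                n_repeats=1, seed=int(rng.integers(2**31)),
                                neuron_pool=idx)
            elif task == "side":
                r = decode_side(pop, n_neurons=n_neurons, n_repeats=1,
                                seed=int(rng.integers(2**31)), neuron_pool=idx)
            else:
                raise ValueError(f"unknown task {task!r}")
            accs[rep] = r.accuracy_mean
        results.append(DecodingResult(
            accuracy_mean=float(accs.mean()), accuracy_sd=float(accs.std(ddof=0)),
            n_neurons=n_neurons, n_repeats=n_repeats, train_side=train_side,
            test_side=test_side, chance=(1.0 / pop.n_odors if task == "odor" else 0.5),
            accuracies=accs,
        ))
    return results


def match_centroids(
    centroids_a: np.ndarray, centroids_b: np.ndarray, metric: str = "euclidean"
) -> float:
    """Trial-free odor decoding between two sets of P odor centroids.

    Each centroid in ``centroids_a`` (rows = odors) is assigned independently
    to its nearest neighbor among ``centroids_b``; the accuracy is the
    fraction of odors assigned to the same odor index.  The angular metric
    uses cosine distance and counts zero vectors as incorrect.
    """
    a = np.asarray(centroids_a, dtype=float)
    b = np.asarray(centroids_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("centroid sets must have equal shape (odors x neurons)")
    P = a.shape[0]
    if metric == "euclidean":
        assign = _nearest(a, b)
        return float(np.mean(assign == np.arange(P)))
    if metric == "angular":
        na = np.linalg.norm(a, axis=1)
        nb = np.linalg.norm(b, axis=1)
        ok = (na > 0) & np.all(nb > 0)
        cos = np.zeros((P, P))
        nz = nb > 0
        cos[:, nz] = (a @ b[nz].T) / np.outer(np.where(na > 0, na, 1.0), nb[nz])
        assign = cos.argmax(axis=1)
        return float(np.mean(ok & (assign == np.arange(P))))
    raise ValueError(f"unknown metric {metric!r}")


def classify_side_centroid(
    ipsi_centroids: np.ndarray, contra_centroids: np.ndarray
) -> float:
    """Leave-one-odor-out side classification from the 2P odor centroids.

    For each odor, both of its centroids are removed; the remaining P-1
    centroids per side are averaged into a side mean, and the two removed
    centroids are classified to the nearer mean.  Accuracy over 2P decisions.
    """
    a = np.asarray(ipsi_centroids, dtype=float)
    b = np.asarray(contra_centroids, dtype=float)
    if a.shape != b.shape:
        raise ValueError("centroid sets must have equal shape")
    P = a.shape[0]
    if P < 2:
        raise ValueError("need at least 2 odors for leave-one-odor-out")
    sum_a, sum_b = a.sum(axis=0), b.sum(axis=0)
    correct = 0
    for o in range(P):
        mean_a = (sum_a - a[o]) / (P - 1)
        mean_b = (sum_b - b[o]) / (P - 1)
        means = np.stack([mean_a, mean_b], axis=0)
        correct += int(_nearest(a[o][None, :], means)[0] == 0)
        correct += int(_nearest(b[o][None, :], means)[0] == 1)
    return correct / (2.0 * P)
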