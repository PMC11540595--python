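"""Two-hemisphere thresholded-Gaussian model of olfactory cortex.

Each cortical neuron receives a random projection of the glomerular odor
responses; by the central limit theorem its input vector across the P odors
is zero-mean Gaussian with covariance gamma^2 * cos(theta), where cos(theta)
is the odor-odor cosine-similarity matrix of the glomerular panel.  The
response is the shrink nonlinearity (symmetric soft threshold at phi), so the
fraction of active neuron-odor pairs obeys S = erfc(phi / (gamma * sqrt(2))):
the target sparseness fixes phi/gamma, and gamma (the units-to-Hz conversion)
is fit to the tail of significant response magnitudes.

The two cortices are linked by G = alpha * G_Struct + (1 - alpha) * G_Rand,
mixing a Hebbian covariance-rule matrix (outer products of centroid-subtracted
odor responses) with a sparse random matrix, rescaled (chi) so both parts
drive outputs of equal summed magnitude.  The contralateral representation is
shrink(s * G * Y_opp) with s chosen by bisection to hit the contralateral
sparseness.  Alignment between hemispheres is summarized by four metrics
(pooled correlation, BCN fraction, centroid odor-matching accuracy, side
accuracy) sampled over subpopulations, and alpha is fit by minimizing the
z^2 distance between model and observed metrics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import erfcinv

from .bilateral import ols_f_test
from .decoding import classify_side_centroid, match_centroids
from .synthdata import GlomerularPanel

__all__ = [
    "ModelConfig",
    "CortexResponses",
    "CrossConnectivity",
    "AlignmentMetrics",
    "METRIC_NAMES",
    "shrink",
    "calibrate_threshold",
    "fit_gamma",
    "sample_ipsilateral_cortex",
    "build_random_matrix",
    "build_hebbian_matrix",
    "rescale_and_mix",
    "generate_contralateral",
    "lowrank_struct_svd",
    "lowrank_struct_pca",
    "compute_alignment_metrics",
    "fit_alpha",
    "simulate_bilateral_cortices",
]

METRIC_NAMES = ("pooled_r", "bcn_fraction", "odor_match_accuracy", "side_accuracy")


def shrink(h, phi: float):
    """Symmetric soft threshold: h -> h -/+ phi outside the dead zone, else 0."""
    if phi < 0:
        raise ValueError("threshold must be nonnegative")
    h = np.asarray(h, dtype=float)
    out = np.where(h >= phi, h - phi, np.where(h <= -phi, h + phi, 0.0))
    return out if out.ndim else float(out)


def calibrate_threshold(sparseness: float) -> float:
    """phi/gamma ratio achieving a target active fraction: sqrt(2)*erfcinv(S)."""
    if not 0.0 < sparseness < 1.0:
        raise ValueError("sparseness must lie in (0, 1)")
    return math.sqrt(2.0) * float(erfcinv(sparseness))


def fit_gamma(significant_magnitudes: np.ndarray, phi_over_gamma: float) -> float:
    """Maximum-likelihood gamma for the Gaussian-tail magnitude law.

    Significant response magnitudes m >= 0 follow
    p(m) proportional to exp(-(m + phi)^2 / (2 gamma^2)) with phi tied to
    gamma through the sparseness calibration (phi = ratio * gamma).  With that
    tie the normalizer is proportional to gamma, so the negative log-likelihood
    is n*log(gamma) + sum((m + ratio*gamma)^2) / (2 gamma^2), minimized in 1-D.
    At ratio 0 this is the half-normal MLE, gamma^2 = mean(m^2).
    """
    m = np.asarray(significant_magnitudes, dtype=float)
    if m.size == 0 or np.any(m <= 0):
        raise ValueError("magnitudes must be positive and nonempty")
    rho = float(phi_over_gamma)
    scale = float(np.sqrt(np.mean(m**2)))

    def nll(g: float) -> float:
        return m.size * math.log(g) + float(np.sum((m + rho * g) ** 2)) / (2 * g * g)

    res = minimize_scalar(nll, bounds=(1e-9 * scale + 1e-12, 50 * scale),
                          method="bounded", options={"xatol": 1e-10 * scale})
    return float(res.x)


@dataclass
class ModelConfig:
    """Parameters of the two-hemisphere model (region preset: AON).

    ``n_neurons`` defaults to the modeled AON size (50,000); analyses in this
    package typically run at 2,000-5,000 neurons, which leaves the fitted
    alpha unchanged (the model is robust to population size).
    """

    n_neurons: int = 50_000
    n_glomeruli: int = 155
    n_odors: int = 15
    gamma: float = 3.5  # Hz per model unit
    sparseness_ipsi: float = 0.224
    sparseness_contra: float = 0.252
    xi: float = 0.5  # connection probability of the random component
    sigma: float = 1.0
    alpha: float = 0.42
    Q: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if not 0.0 < self.xi <= 1.0:
            raise ValueError("xi must lie in (0, 1]")
        for s in (self.sparseness_ipsi, self.sparseness_contra):
            if not 0.0 < s < 1.0:
                raise ValueError("sparseness must lie in (0, 1)")

    @property
    def phi(self) -> float:
        """Threshold implied by gamma and the ipsilateral sparseness."""
        return self.gamma * calibrate_threshold(self.sparseness_ipsi)


@dataclass
class CortexResponses:
    """Pre-activation inputs h and post-shrink responses y, (n_neurons, P)."""

    h: np.ndarray
    y: np.ndarray
    phi: float
    scale: float = 1.0  # contralateral sparseness rescaling, 1 for ipsilateral

    @property
    def n_neurons(self) -> int:
        return self.y.shape[0]

    @property
    def n_odors(self) -> int:
        return self.y.shape[1]

    @property
    def centroid(self) -> np.ndarray:
        """Per-neuron odor-mean response."""
        return self.y.mean(axis=1)

    @property
    def sparseness(self) -> float:
        return float(np.mean(self.y != 0))


@dataclass
class CrossConnectivity:
    """Mixed random/Hebbian cross-cortical link G = a*G_struct + (1-a)*G_rand."""

    G_rand: np.ndarray
    G_struct_unscaled: np.ndarray
    chi: float
    alpha: float
    G_struct: np.ndarray = field(repr=False, default=None)
    G: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.G_struct is None:
            self.G_struct = self.chi * self.G_struct_unscaled
        if self.G is None:
            self.G = self.alpha * self.G_struct + (1.0 - self.alpha) * self.G_rand


@dataclass
class AlignmentMetrics:
    """Model/data comparison statistics with sampling SDs over subpopulations."""

    pooled_r: float
    bcn_fraction: float
    odor_match_accuracy: float
    side_accuracy: float
    sds: dict = field(default_factory=dict)
    samples: dict = field(default_factory=dict, repr=False)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in METRIC_NAMES])

    def sd_array(self) -> np.ndarray:
        return np.array([self.sds[k] for k in METRIC_NAMES])


def _psd_project(cov: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Clip negative eigenvalues to zero; fail if the matrix is far from PSD."""
    cov = 0.5 * (cov + cov.T)
    w, v = np.linalg.eigh(cov)
    if w.min() < -tol * max(1.0, w.max()):
        raise ValueError("covariance is not positive semidefinite within tolerance")
    w = np.clip(w, 0.0, None)
    return (v * w) @ v.T


def sample_ipsilateral_cortex(
    panel: GlomerularPanel,
    config: ModelConfig,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> CortexResponses:
    """Draw cortical responses to ipsilaterally presented odors.

    Each neuron's P-vector of inputs is i.i.d. N(0, gamma^2 * cos_theta)
    (the CLT limit of random glomerulus-to-cortex projections); responses are
    the shrink of the inputs at the calibrated threshold.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    cov = config.gamma**2 * _psd_project(panel.cos_theta)
    L = np.linalg.cholesky(cov + 1e-12 * config.gamma**2 * np.eye(cov.shape[0]))
    z = rng.standard_normal((config.n_neurons, panel.n_odors))
    h = z @ L.T
    return CortexResponses(h=h, y=shrink(h, config.phi), phi=config.phi)


def build_random_matrix(n: int, xi: float, seed: int | None = None,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """n x n matrix of N(0, 1) entries kept with probability xi, else 0."""
    if not 0.0 < xi <= 1.0:
        raise ValueError("xi must lie in (0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    g = rng.standard_normal((n, n))
    if xi < 1.0:
        g *= rng.random((n, n)) < xi
    return g


def build_hebbian_matrix(ipsi: CortexResponses, opp: CortexResponses) -> np.ndarray:
    """Covariance-rule Hebbian link: sum over odors of centered outer products.

    G = sum_o (Y_o^ipsi - C^ipsi)(Y_o^opp - C^opp)^T; rank at most P - 1.
    """
    if ipsi.n_odors != opp.n_odors:
        raise ValueError("cortices must share the odor count")
    a = ipsi.y - ipsi.centroid[:, None]
    b = opp.y - opp.centroid[:, None]
    return a @ b.T


def rescale_and_mix(
    G_struct_unscaled: np.ndarray,
    G_rand: np.ndarray,
    opp_responses: CortexResponses,
    alpha: float,
) -> CrossConnectivity:
    """Equalize the two components' output magnitudes and mix with alpha.

    chi = sum_o |G_rand Y_o^opp| / sum_o |G_struct_unscaled Y_o^opp| so that,
    after rescaling, the structured and random parts drive outputs of equal
    summed Euclidean norm; then G = alpha * G_struct + (1 - alpha) * G_rand.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    y = opp_responses.y
    num = float(np.linalg.norm(G_rand @ y, axis=0).sum())
    den = float(np.linalg.norm(G_struct_unscaled @ y, axis=0).sum())
    if den == 0.0:
        raise ValueError("structured output norm is zero (degenerate responses)")
    chi = num / den
    return CrossConnectivity(G_rand=G_rand, G_struct_unscaled=G_struct_unscaled,
                             chi=chi, alpha=alpha)


def generate_contralateral(
    opp: CortexResponses,
    conn: CrossConnectivity | np.ndarray,
    phi: float,
    target_sparseness: float,
    tol: float = 0.005,
    max_iter: int = 60,
) -> CortexResponses:
    """Map the opposite cortex through G and rescale to the target sparseness.

    The mapped input s * G * Y^opp is thresholded with the same phi used
    ipsilaterally; the scalar s is found by log-scale bisection on
    s in [1e-6, 1e6] so the realized active fraction is within ``tol`` of the
    target.  Sparseness is monotone in s, so bisection is exact up to the
    1/(n*P) granularity of the empirical fraction.
    """
    if not 0.0 < target_sparseness < 1.0:
        raise ValueError("target sparseness must lie in (0, 1)")
    G = conn.G if isinstance(conn, CrossConnectivity) else conn
    H = G @ opp.y

    def sparseness(log_s: float) -> float:
        return float(np.mean(np.abs(H) * 10.0**log_s >= phi))

    lo, hi = -6.0, 6.0
    s_lo, s_hi = sparseness(lo), sparseness(hi)
    if not (s_lo <= target_sparseness <= s_hi):
        raise ValueError(
            f"target sparseness {target_sparseness} unreachable; achievable "
            f"range [{s_lo:.4f}, {s_hi:.4f}] over s in [1e-6, 1e6]"
        )
    mid = 0.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        s_mid = sparseness(mid)
        if abs(s_mid - target_sparseness) <= tol:
            break
        if s_mid < target_sparseness:
            lo = mid
        else:
            hi = mid
    s = 10.0**mid
    achieved = sparseness(mid)
    if abs(achieved - target_sparseness) > tol:
        raise ValueError(
            f"bisection failed to reach sparseness {target_sparseness} "
            f"(achieved {achieved:.4f}) within tolerance {tol}"
        )
    h = s * H
    return CortexResponses(h=h, y=shrink(h, phi), phi=phi, scale=s)


def lowrank_struct_svd(
    G_struct: np.ndarray, Q: int,
    factors: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Best rank-Q Frobenius approximation of the structured matrix via SVD.

    Pass precomputed ``factors`` (U, s, Vt) to amortize the decomposition over
    a Q sweep.
    """
    if factors is None:
        factors = np.linalg.svd(G_struct, full_matrices=False)
    U, s, Vt = factors
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if not 1 <= Q <= max(rank, 1):
        raise ValueError(f"Q={Q} outside [1, rank={rank}]")
    return (U[:, :Q] * s[:Q]) @ Vt[:Q]


def lowrank_struct_pca(ipsi: CortexResponses, opp: CortexResponses, Q: int,
                       return_info: bool = False):
    """Hebbian alignment of the opposite cortex's first Q principal components.

    The PCs of the centered opposite-cortex odor responses give coefficient
    vectors rho_q over odors; the same coefficients are applied to the
    ipsilateral responses, and G = sum_q Y_q^ipsi (Y_q^opp)^T.  With Q = P
    (all components) the construction spans the full Hebbian matrix.
    """
    P = opp.n_odors
    if not 1 <= Q <= P:
        raise ValueError(f"Q={Q} outside [1, P={P}]")
    b = opp.y - opp.centroid[:, None]  # centered over odors
    a = ipsi.y - ipsi.centroid[:, None]
    gram = b.T @ b  # (P, P)
    w, v = np.linalg.eigh(gram)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]  # columns are rho_q
    rho = v[:, :Q]
    G = (a @ rho) @ (b @ rho).T
    if return_info:
        total = float(np.sum(np.clip(w, 0, None)))
        explained = float(np.sum(np.clip(w[:Q], 0, None))) / total if total > 0 else 0.0
        return G, {"eigenvalues": w, "variance_explained": explained, "rho": v}
    return G


def _bcn_fraction_trial_free(yi: np.ndarray, yc: np.ndarray, alpha: float = 0.05) -> float:
    _, _, _, p, valid = ols_f_test(yi, yc)
    return float(np.mean(valid & (p < alpha)))


def _pooled_r(yi: np.ndarray, yc: np.ndarray) -> float:
    a, b = yi.ravel(), yc.ravel()
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def compute_alignment_metrics(
    ipsi: CortexResponses,
    contra: CortexResponses,
    n_sample: int = 385,
    n_reps: int = 200,
    seed: int = 0,
    metric: str = "euclidean",
) -> AlignmentMetrics:
    """Four cross-cortical alignment statistics over sampled subpopulations.

    Per sample of ``n_sample`` neurons (the recorded AON population size):
    pooled Pearson r over all (neuron, odor) response pairs; the BCN fraction
    from trial-free per-neuron contra~ipsi regressions; centroid
    odor-matching accuracy (each contralateral odor centroid assigned to its
    nearest ipsilateral neighbor); and leave-one-odor-out side classification
    accuracy.  Means and SDs over ``n_reps`` samples.
    """
    n = ipsi.n_neurons
    if contra.n_neurons != n or contra.n_odors != ipsi.n_odors:
        raise ValueError("cortices must share neurons and odors")
    if n_sample > n:
        raise ValueError(f"cannot sample {n_sample} of {n} neurons")
    rng = np.random.default_rng(seed)
    samples = {k: np.empty(n_reps) for k in METRIC_NAMES}
    for rep in range(n_reps):
        idx = rng.choice(n, n_sample, replace=False)
        yi, yc = ipsi.y[idx], contra.y[idx]
        samples["pooled_r"][rep] = _pooled_r(yi, yc)
        samples["bcn_fraction"][rep] = _bcn_fraction_trial_free(yi, yc)
        samples["odor_match_accuracy"][rep] = match_centroids(yc.T, yi.T, metric=metric)
        samples["side_accuracy"][rep] = classify_side_centroid(yi.T, yc.T)
    means = {k: float(v.mean()) for k, v in samples.items()}
    sds = {k: float(v.std(ddof=0)) for k, v in samples.items()}
    return AlignmentMetrics(**means, sds=sds, samples=samples)


def simulate_bilateral_cortices(
    panel: GlomerularPanel,
    config: ModelConfig,
    alpha: float | None = None,
    seed: int | None = None,
    lowrank: str = "none",
    hebbian_from: str = "both",
    shared: dict | None = None,
) -> tuple[CortexResponses, CortexResponses]:
    """Two-realization protocol: ipsi-A vs contra = shrink(s * G * ipsi-B).

    Two independent ipsilateral realizations are drawn; realization B (the
    opposite cortex's own responses) is mapped through G to produce the
    contralateral representation, and realization A is the comparison ipsi.
    The Hebbian component pairs A with B (``hebbian_from="both"``, the
    covariance rule over shared odor experience) or B with itself
    (``"opp"``).  ``lowrank`` in {"none", "svd", "pca"} applies the rank-Q
    approximation with Q = config.Q.  Passing a dict as ``shared`` caches the
    realizations and component matrices across calls (used by the alpha scan).
    """
    a = config.alpha if alpha is None else alpha
    if shared is None:
        shared = {}
    if "ipsi_a" not in shared:
        rng = np.random.default_rng(config.seed if seed is None else seed)
        ipsi_a = sample_ipsilateral_cortex(panel, config, rng=rng)
        ipsi_b = sample_ipsilateral_cortex(panel, config, rng=rng)
        G_rand = build_random_matrix(config.n_neurons, config.xi, rng=rng)
        heb_ipsi = ipsi_a if hebbian_from == "both" else ipsi_b
        G_struct_u = build_hebbian_matrix(heb_ipsi, ipsi_b)
        if lowrank == "svd":
            G_struct_u = lowrank_struct_svd(G_struct_u, config.Q)
        elif lowrank == "pca":
            G_struct_u = lowrank_struct_pca(heb_ipsi, ipsi_b, config.Q)
        elif lowrank != "none":
            raise ValueError(f"unknown lowrank scheme {lowrank!r}")
        shared.update(ipsi_a=ipsi_a, ipsi_b=ipsi_b, G_rand=G_rand, G_struct_u=G_struct_u)
    conn = rescale_and_mix(shared["G_struct_u"], shared["G_rand"], shared["ipsi_b"], a)
    contra = generate_contralateral(shared["ipsi_b"], conn, config.phi,
                                    config.sparseness_contra)
    return shared["ipsi_a"], contra


@dataclass
class AlphaFit:
    alpha_star: float
    alpha_grid: np.ndarray
    z2: np.ndarray
    metrics_by_alpha: list[AlignmentMetrics]


def fit_alpha(
    data_metrics: np.ndarray | dict,
    panel: GlomerularPanel,
    config: ModelConfig,
    alpha_grid: np.ndarray | None = None,
    seed: int = 0,
    n_sample: int = 385,
    n_reps: int = 200,
    lowrank: str = "none",
) -> AlphaFit:
    """Fit the structure weight alpha by minimizing the z^2 score.

    For each alpha on the grid the model is run (same realizations of the
    cortices and component matrices across the scan) and
    z^2 = sum_k ((model_mean_k - data_k) / model_SD_k)^2 over the four
    alignment metrics; the argmin is returned (ties toward smaller alpha;
    metrics with zero model SD are dropped with a notice).
    """
    if isinstance(data_metrics, dict):
        data = np.array([data_metrics[k] for k in METRIC_NAMES])
    else:
        data = np.asarray(data_metrics, dtype=float)
    if alpha_grid is None:
        alpha_grid = np.round(np.arange(0.0, 1.0 + 1e-9, 0.02), 4)
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    if np.any((alpha_grid < 0) | (alpha_grid > 1)):
        raise ValueError("alpha grid must lie in [0, 1]")
    order = np.argsort(alpha_grid, kind="stable")  # ties -> smaller alpha wins argmin
    alpha_grid = alpha_grid[order]

    shared: dict = {}
    z2 = np.empty(alpha_grid.size)
    all_metrics: list[AlignmentMetrics] = []
    for k, a in enumerate(alpha_grid):
        ipsi, contra = simulate_bilateral_cortices(panel, config, alpha=float(a),
                                                   seed=seed, lowrank=lowrank,
                                                   shared=shared)
        m = compute_alignment_metrics(ipsi, contra, n_sample=n_sample,
                                      n_reps=n_reps, seed=(seed, k))
        mean, sd = m.as_array(), m.sd_array()
        use = sd > 0
        if not use.all():
            dropped = [METRIC_NAMES[i] for i in np.flatnonzero(~use)]
            warnings.warn(f"dropping zero-SD metrics from the alpha fit: {dropped}")
        z2[k] = float(np.sum(((mean[use] - data[use]) / sd[use]) ** 2))
        all_metrics.append(m)
    best = int(np.argmin(z2))
    return AlphaFit(alpha_star=float(alpha_grid[best]), alpha_grid=alpha_grid,
                    z2=z2, metrics_by_alpha=all_metrics)
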