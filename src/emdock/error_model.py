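"""Signal- and noise-power estimation from a pair of half-maps.

Matching Fourier terms of the two half-maps are modelled as

    F_1 = S + eps_1,   F_2 = S + eps_2,

where the common signal S and the independent noise terms eps_i are
zero-mean complex normal with variances Sigma_S and Sigma_E.  The joint
distribution of (F_1, F_2) is then a bivariate complex normal with
covariance [[Sigma_S + Sigma_E, Sigma_S], [Sigma_S, Sigma_S + Sigma_E]].
Maximizing the summed log-likelihood over a small neighbourhood in Fourier
space gives analytic estimators:

    Sigma_S_hat = < Re(F_1 conj(F_2)) >        (unnormalized correlation)
    Sigma_E_hat = < |F_1 - F_2|^2 > / 2        (half-map difference power)

Local estimates of Sigma_E are used everywhere (the distribution of
preferred orientations need not obey any symmetry).  For Sigma_S, local
estimates are blended with a refined parametric model

    Sigma_S = A_0^2 exp(-1/2 s^T beta_A s) * m_bin * BEST(s)

via a sigmoid in the local half-map correlation, so that the tensor model
takes over exactly where the local correlation (and hence the local
estimator) becomes unreliable.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.interpolate import PchipInterpolator
from scipy.special import expit

from .fourier_core import (MapGrid, FourierTermSet, _hkl_grids, halfset_mask,
                           local_mean_field, radial_trend, spherical_kernel)

__all__ = [
    "BestCurve",
    "VarianceEstimates",
    "SignalModel",
    "NormalizedData",
    "HalfMapAnalysis",
    "bivariate_loglik",
    "local_ml_variances",
    "sphere_cc",
    "refine_signal_model",
    "hybrid_sigma_s",
    "compute_dobs",
    "normalize",
    "docking_coefficients",
    "analyze_half_maps",
]

SIGMA_E_FLOOR_FRACTION = 1e-10
HYBRID_STEEPNESS = 9.0       # sigmoid steepness for the local/model blend
HYBRID_K0 = 0.95             # correlation pivot of the blend


# ---------------------------------------------------------------------------
# Reference spectrum (BEST-style prior on Sigma_T)

class BestCurve:
    """Tabulated expected signal power versus inverse resolution.

    The shipped default is a synthetic stand-in for the average
    macromolecular power spectrum: a smooth low-resolution falloff with the
    characteristic features near 10 A and 4.5 A.  Any user-supplied
    two-column (s, power) table can be used instead.  Values are
    interpolated monotonically and clamped to the table range.
    """

    def __init__(self, s: np.ndarray, power: np.ndarray):
        s = np.asarray(s, dtype=float)
        power = np.asarray(power, dtype=float)
        if np.any(power <= 0):
            raise ValueError("reference curve must be strictly positive")
        if np.any(np.diff(s) <= 0):
            raise ValueError("s values must be strictly increasing")
        self._s = s
        self._power = power
        self._interp = PchipInterpolator(s, power, extrapolate=False)

    def __call__(self, s):
        s = np.clip(np.asarray(s, dtype=float), self._s[0], self._s[-1])
        return np.asarray(self._interp(s))

    @classmethod
    def synthetic_standin(cls) -> "BestCurve":
        """Synthetic stand-in reference spectrum.

        The original experimental tabulation of the average macromolecular
        power spectrum is not redistributed here.  This stand-in was built
        the same way that curve was: by averaging the power spectra of an
        ensemble of structures — here, compact Gaussian-atom pseudo-
        structures (coil-like chains, 1.2 A atom width) — over many
        realizations, then smoothing.  It shows the generic features such a
        reference needs: a steep small-angle (molecular-shape) rise, the
        favoured-interatomic-distance plateau, and the atom-width falloff.
        For real data, supply the genuine tabulation via ``from_table``.
        The prior is weak by design, so the choice mainly stabilizes
        weak-signal resolution bins.
        """
        table = np.array(_STANDIN_TABLE)
        return cls(table[:, 0], table[:, 1])

    @classmethod
    def from_table(cls, path) -> "BestCurve":
        data = np.loadtxt(path)
        return cls(data[:, 0], data[:, 1])


# Ensemble-average power spectrum of coil-like Gaussian-atom pseudo-
# structures (s in 1/A, relative power); see BestCurve.synthetic_standin.
_STANDIN_TABLE = [
    (0.0201, 504.425), (0.0300, 149.521), (0.0404, 57.6626),
    (0.0501, 42.9744), (0.0589, 28.192), (0.0696, 18.5558),
    (0.0805, 11.9479), (0.0908, 7.81682), (0.1004, 5.47334),
    (0.1105, 3.71717), (0.1207, 2.62698), (0.1305, 1.94575),
    (0.1401, 1.41007), (0.1499, 1.03959), (0.1598, 0.791434),
    (0.1697, 0.609009), (0.1799, 0.479956), (0.1898, 0.388113),
    (0.1998, 0.315834), (0.2099, 0.26145), (0.2201, 0.21693),
    (0.2300, 0.178579), (0.2401, 0.146573), (0.2502, 0.119214),
    (0.2603, 0.096599), (0.2705, 0.0764155), (0.2801, 0.0604509),
    (0.2900, 0.0465367), (0.3001, 0.0347926), (0.3101, 0.0252798),
    (0.3201, 0.0179008), (0.3300, 0.0122958), (0.3403, 0.00825865),
    (0.3502, 0.00548633), (0.3599, 0.0035807), (0.3700, 0.00224995),
    (0.3802, 0.00139634), (0.3901, 0.000855854), (0.4000, 0.000527506),
    (0.4099, 0.000328167), (0.4198, 0.00019678), (0.4298, 0.000118361),
    (0.4399, 7.02546e-05), (0.4500, 4.19758e-05),
]


# ---------------------------------------------------------------------------
# Containers

@dataclasses.dataclass
class VarianceEstimates:
    """Per-term local estimates on the working half-set."""

    sigma_s_local: np.ndarray   # raw local signal power (may be negative)
    sigma_e: np.ndarray         # floored local noise power
    cc_sphere: np.ndarray       # local half-map correlation, in [-1, 1]
    n_neighbourhood: np.ndarray  # terms per neighbourhood


@dataclasses.dataclass
class SignalModel:
    """Parametric signal-power model A0^2 exp(-s^T beta s / 2) m_b BEST(s)."""

    a0: float
    beta: np.ndarray            # symmetric 3x3, A^2
    bin_edges: np.ndarray       # interior s edges, len B-1
    log_multipliers: np.ndarray  # len B, mean fixed to 0
    best: BestCurve
    restraint_weights: np.ndarray
    converged: bool = True
    n_iterations: int = 0

    def bin_index(self, s) -> np.ndarray:
        return np.searchsorted(self.bin_edges, np.asarray(s, dtype=float))

    def predict(self, svec: np.ndarray) -> np.ndarray:
        """Sigma_S at s-vectors (n, 3) in 1/A."""
        svec = np.atleast_2d(np.asarray(svec, dtype=float))
        s = np.linalg.norm(svec, axis=1)
        q = np.einsum("ni,ij,nj->n", svec, self.beta, svec)
        mult = np.exp(self.log_multipliers)[self.bin_index(s)]
        return self.a0 ** 2 * np.exp(-0.5 * q) * mult * self.best(s)


@dataclasses.dataclass
class NormalizedData:
    """Normalized averaged coefficients E_mean with their D_obs weights."""

    terms: FourierTermSet       # F_mean on the working half-set
    e_mean: np.ndarray
    d_obs: np.ndarray
    sigma_s: np.ndarray         # hybrid, floored
    sigma_e: np.ndarray

    def __len__(self):
        return len(self.e_mean)

    def select(self, mask: np.ndarray) -> "NormalizedData":
        return NormalizedData(self.terms.select(mask), self.e_mean[mask],
                              self.d_obs[mask], self.sigma_s[mask],
                              self.sigma_e[mask])


# ---------------------------------------------------------------------------
# Likelihood of a half-map Fourier pair

def bivariate_loglik(f1, f2, sigma_s, sigma_e):
    """Log joint density of matching half-map terms (F_1, F_2).

    The covariance has diagonal Sigma_S + Sigma_E and off-diagonal Sigma_S;
    determinant Sigma_E (2 Sigma_S + Sigma_E).  Works elementwise on arrays.
    """
    f1 = np.asarray(f1, dtype=np.complex128)
    f2 = np.asarray(f2, dtype=np.complex128)
    sigma_s = np.asarray(sigma_s, dtype=float)
    sigma_e = np.asarray(sigma_e, dtype=float)
    det = sigma_e * (2.0 * sigma_s + sigma_e)
    if np.any(det <= 0) or np.any(sigma_s + sigma_e <= 0):
        raise ValueError("covariance matrix not positive definite")
    a = np.abs(f1) ** 2 + np.abs(f2) ** 2
    b = (f1 * np.conj(f2)).real
    quad = ((sigma_s + sigma_e) * a - 2.0 * sigma_s * b) / det
    return -2.0 * np.log(np.pi) - np.log(det) - quad


def _neighbourhood(terms1: FourierTermSet, terms2: FourierTermSet,
                   centre_hkl, radius_terms: int):
    """Friedel-expanded coefficients within an hkl-sphere of the centre."""
    if len(terms1) != len(terms2) or not np.array_equal(terms1.hkl, terms2.hkl):
        raise ValueError("half-map term sets must share an hkl index")
    centre = np.asarray(centre_hkl, dtype=int)
    hkl = np.vstack([terms1.hkl, -terms1.hkl])
    f1 = np.concatenate([terms1.f, np.conj(terms1.f)])
    f2 = np.concatenate([terms2.f, np.conj(terms2.f)])
    # drop the duplicated self-conjugate origin if present
    keep = np.ones(len(hkl), dtype=bool)
    zero = np.all(terms1.hkl == 0, axis=1)
    if zero.any():
        keep[len(terms1) + np.nonzero(zero)[0]] = False
    d2 = np.sum((hkl - centre) ** 2, axis=1)
    sel = keep & (d2 <= radius_terms ** 2)
    return f1[sel], f2[sel]


def local_ml_variances(terms1: FourierTermSet, terms2: FourierTermSet,
                       centre_hkl, radius_terms: int, n_min: int = 20):
    """Analytic ML estimates of (Sigma_S, Sigma_E) in one hkl neighbourhood.

    These maximize the summed bivariate log-likelihood exactly: rotating to
    the independent combinations (F_1 +/- F_2)/sqrt(2) with variances
    2 Sigma_S + Sigma_E and Sigma_E reduces the problem to two complex-normal
    scale estimates.  The raw Sigma_S may be negative; flooring happens when
    it is consumed downstream.
    """
    f1, f2 = _neighbourhood(terms1, terms2, centre_hkl, radius_terms)
    if len(f1) < n_min:
        raise ValueError(
            f"neighbourhood holds {len(f1)} terms; at least {n_min} required")
    sigma_s = float(np.mean((f1 * np.conj(f2)).real))
    sigma_e = float(np.mean(np.abs(f1 - f2) ** 2) / 2.0)
    return sigma_s, sigma_e


def sphere_cc(terms1: FourierTermSet, terms2: FourierTermSet,
              centre_hkl, radius_terms: int, n_min: int = 20) -> float:
    """Local Fourier sphere correlation (real part), clipped to [-1, 1]."""
    f1, f2 = _neighbourhood(terms1, terms2, centre_hkl, radius_terms)
    if len(f1) < n_min:
        raise ValueError(
            f"neighbourhood holds {len(f1)} terms; at least {n_min} required")
    p1 = np.mean(np.abs(f1) ** 2)
    p2 = np.mean(np.abs(f2) ** 2)
    if p1 <= 0 or p2 <= 0:
        raise ValueError("zero-power neighbourhood")
    cc = np.mean((f1 * np.conj(f2)).real) / np.sqrt(p1 * p2)
    return float(np.clip(cc, -1.0, 1.0))


# ---------------------------------------------------------------------------
# Field-wise local estimation (circular convolution over the fftn grid)

def local_variance_fields(F1: np.ndarray, F2: np.ndarray, valid: np.ndarray,
                          radius: int, trend_total=None, trend_diff=None):
    """Local ML variance and correlation fields for every grid term at once.

    Neighbourhood means are circular convolutions with a spherical kernel in
    index space, normalized by the convolved validity mask, so terms outside
    the resolution cutoff never contribute.

    ``trend_total``/``trend_diff`` optionally pre-whiten the signal-bearing
    and difference fields by their radial trends before averaging (and
    restore them after): without this, the arithmetic neighbourhood mean of
    the steeply falling low-resolution power overestimates the value at the
    neighbourhood centre by a large factor.
    """
    kernel_ft = np.fft.fftn(spherical_kernel(F1.shape, radius))

    def conv(x):
        return np.fft.ifftn(np.fft.fftn(x) * kernel_ft).real

    tt = np.ones_like(valid, dtype=float) if trend_total is None else trend_total
    td = np.ones_like(valid, dtype=float) if trend_diff is None else trend_diff
    m = valid.astype(float)
    counts = conv(m)
    counts_safe = np.maximum(counts, 1e-9)
    cross = conv((F1 * np.conj(F2)).real / tt * m) / counts_safe
    diff = conv(np.abs(F1 - F2) ** 2 / td * m) / counts_safe
    p1 = conv(np.abs(F1) ** 2 / tt * m) / counts_safe
    p2 = conv(np.abs(F2) ** 2 / tt * m) / counts_safe
    with np.errstate(invalid="ignore", divide="ignore"):
        cc = cross / np.sqrt(np.maximum(p1 * p2, 1e-300))
    return {
        "sigma_s": cross * tt,
        "sigma_e": diff * td / 2.0,
        "cc": np.clip(np.nan_to_num(cc), -1.0, 1.0),
        "counts": np.rint(counts).astype(int),
    }


# ---------------------------------------------------------------------------
# Parametric signal model refinement

def refine_signal_model(terms1: FourierTermSet, terms2: FourierTermSet,
                        sigma_e: np.ndarray, best: Optional[BestCurve] = None,
                        bins: int = 20, restraint_base: float = 10.0,
                        restraint_slope: float = 4.0, max_iter: int = 1000,
                        tol: float = 1e-8, max_terms: int = 40000) -> SignalModel:
    """Fit A0, beta_A and restrained binwise Sigma_T multipliers by ML.

    Maximizes the summed half-map pair log-likelihood with
    Sigma_S = A0^2 exp(-s^T beta s / 2) * m_b * BEST(s) and Sigma_E held at
    its local estimates, minus a quadratic restraint on log m_b pulling the
    multipliers to one.  Restraints grow linearly (factor ``restraint_slope``)
    from the lowest- to the highest-resolution bin: low-resolution terms
    reflect molecular shape and are allowed to stray further from the
    reference spectrum.  The mean log-multiplier is pinned to zero so the
    overall scale lives in A0 alone.
    """
    if bins < 5:
        raise ValueError("at least 5 resolution bins required")
    if best is None:
        best = BestCurve.synthetic_standin()
    mask = terms1.s > 0
    s = terms1.s[mask]
    box = terms1.cell
    svec = terms1.hkl[mask] / box[None, :]
    a_pow = (np.abs(terms1.f[mask]) ** 2 + np.abs(terms2.f[mask]) ** 2)
    b_pow = (terms1.f[mask] * np.conj(terms2.f[mask])).real
    se = np.asarray(sigma_e, dtype=float)[mask]
    se = np.maximum(se, SIGMA_E_FLOOR_FRACTION * max(a_pow.mean(), 1e-300))

    # equal-count bins over the working terms
    order = np.argsort(s, kind="stable")
    edges = np.array([s[order[int(len(s) * k / bins)]]
                      for k in range(1, bins)])
    bin_idx = np.searchsorted(edges, s)
    weights = restraint_base * (1.0 + (restraint_slope - 1.0)
                                * np.arange(bins) / (bins - 1))

    if len(s) > max_terms:          # subsample for speed; estimators stay ML
        stride = int(np.ceil(len(s) / max_terms))
        sub = slice(None, None, stride)
        s_f, svec_f, a_f, b_f, se_f, bin_f = (s[sub], svec[sub], a_pow[sub],
                                              b_pow[sub], se[sub], bin_idx[sub])
    else:
        s_f, svec_f, a_f, b_f, se_f, bin_f = s, svec, a_pow, b_pow, se, bin_idx

    best_f = np.asarray(best(s_f))
    # tensor entries are fitted in units of 1/<s^2> so that all parameters
    # have comparable scales (conditioning of the quasi-Newton steps)
    beta_scale = 1.0 / float((s_f ** 2).mean())
    sq = (svec_f[:, :, None] * svec_f[:, None, :]) * beta_scale

    # identifiability: the multipliers carry neither an overall scale (A0's
    # job) nor a quadratic falloff in s (the tensor's job) — project the
    # [1, s^2] components out of the log-multiplier vector
    qb = np.array([np.mean(s_f[bin_f == b] ** 2) if np.any(bin_f == b)
                   else 0.0 for b in range(bins)])
    X = np.column_stack([np.ones(bins), qb - qb.mean()])
    proj = np.eye(bins) - X @ np.linalg.solve(X.T @ X, X.T)

    # Initialize from the binwise local cross-correlation estimates: the
    # optimizer then only reallocates between the tensor and the
    # multipliers instead of climbing out of the collapsed-signal valley.
    floor_b = 1e-4 * max(float(np.abs(b_f).mean()), 1e-300)
    u_init = np.empty(bins)
    for b in range(bins):
        sel = bin_f == b
        u_init[b] = np.log(max(b_f[sel].mean(), floor_b)
                           / max(best_f[sel].mean(), 1e-300))
    a0_init = np.exp(0.5 * u_init.mean())

    def unpack(p):
        ln_a0 = p[0]
        beta = np.array([[p[1], p[4], p[5]],
                         [p[4], p[2], p[6]],
                         [p[5], p[6], p[3]]])
        return ln_a0, beta, proj @ p[7:]

    def objective(p):
        ln_a0, beta, uc = unpack(p)
        q = np.einsum("nij,ij->n", sq, beta)
        log_ss = 2.0 * ln_a0 - 0.5 * q + uc[bin_f]
        ss = np.exp(log_ss) * best_f
        det = se_f * (2.0 * ss + se_f)
        quad = ((ss + se_f) * a_f - 2.0 * ss * b_f) / det
        nll = np.sum(np.log(det) + quad)
        restraint = np.sum(weights * uc ** 2)
        # gradient wrt Sigma_S per term
        dquad = ((a_f - 2.0 * b_f) * det
                 - ((ss + se_f) * a_f - 2.0 * ss * b_f) * 2.0 * se_f) / det ** 2
        dnll_dss = 2.0 * se_f / det + dquad
        g_ss = dnll_dss * ss            # wrt log Sigma_S
        grad = np.zeros_like(p)
        grad[0] = 2.0 * np.sum(g_ss)
        gb = -0.5 * np.einsum("n,nij->ij", g_ss, sq)
        grad[1:4] = np.diag(gb)
        grad[4] = 2.0 * gb[0, 1]
        grad[5] = 2.0 * gb[0, 2]
        grad[6] = 2.0 * gb[1, 2]
        gu = np.bincount(bin_f, weights=g_ss, minlength=bins)
        gu = gu + 2.0 * weights * uc
        grad[7:] = proj.T @ gu          # chain rule through the projection
        return nll + restraint, grad

    p0 = np.zeros(7 + bins)
    p0[0] = np.log(a0_init)
    p0[7:] = u_init
    # seed the tensor's isotropic part with the quadratic slope that the
    # projection removes from the multipliers
    slope = np.linalg.solve(X.T @ X, X.T @ u_init)[1]
    p0[1:4] = -2.0 * slope / beta_scale
    res = optimize.minimize(objective, p0, jac=True, method="L-BFGS-B",
                            options={"maxiter": max_iter, "ftol": tol,
                                     "gtol": 1e-8})
    if not res.success:
        warnings.warn(f"signal-model refinement did not fully converge: "
                      f"{res.message}", RuntimeWarning)
    ln_a0, beta, uc = unpack(res.x)
    beta = beta * beta_scale
    return SignalModel(a0=float(np.exp(ln_a0)), beta=beta, bin_edges=edges,
                       log_multipliers=uc, best=best,
                       restraint_weights=weights, converged=bool(res.success),
                       n_iterations=int(res.nit))


# ---------------------------------------------------------------------------
# Hybrid signal estimate, D_obs, normalization

def hybrid_sigma_s(local, model, cc, steepness: float = HYBRID_STEEPNESS,
                   k0: float = HYBRID_K0):
    """Sigmoid-weighted blend of local and tensor-model signal power.

    The local estimate carries weight w = logistic(steepness * (cc - k0)),
    so the tensor model dominates wherever the local half-map correlation is
    low, and still contributes (w ~ 0.62) even at cc = 1.  The blend is
    floored at zero.
    """
    w = expit(steepness * (np.asarray(cc, dtype=float) - k0))
    out = w * np.asarray(local, float) + (1.0 - w) * np.asarray(model, float)
    return np.maximum(out, 0.0)


def compute_dobs(sigma_s, sigma_e):
    """D_obs = sqrt(Sigma_S / (Sigma_S + Sigma_E / 2)), in [0, 1].

    Averaging the half-maps halves the noise variance; D_obs is the complex
    correlation between the normalized averaged coefficient and the truth
    implied by that covariance.
    """
    ss = np.maximum(np.asarray(sigma_s, dtype=float), 0.0)
    se = np.asarray(sigma_e, dtype=float)
    if np.any(se <= 0):
        raise ValueError("sigma_e must be floored to a positive value")
    return np.sqrt(ss / (ss + se / 2.0))


def normalize(terms_mean: FourierTermSet, sigma_s, sigma_e,
              norm_power=None) -> NormalizedData:
    """E_mean = F_mean / sqrt(Sigma_S + Sigma_E/2); shell <|E|^2> ~ 1.

    ``norm_power`` optionally supplies the Sigma_S + Sigma_E/2 normalizer
    directly.  The analysis pipeline passes the local mean of |F_mean|^2,
    which is algebraically identical to the local ML estimate of
    Sigma_S + Sigma_E/2 (and guaranteed non-negative); the hybrid Sigma_S
    is then used only for D_obs, where the model's stability matters.
    """
    ss = np.maximum(np.asarray(sigma_s, dtype=float), 0.0)
    se = np.asarray(sigma_e, dtype=float)
    if norm_power is None:
        norm_power = ss + se / 2.0
    denom = np.sqrt(np.asarray(norm_power, dtype=float))
    if np.any(denom <= 0):
        raise ValueError("vanishing normalizer; floor sigma_e first")
    e_mean = terms_mean.f / denom
    return NormalizedData(terms=terms_mean, e_mean=e_mean,
                          d_obs=compute_dobs(ss, se), sigma_s=ss, sigma_e=se)


def docking_coefficients(norm: NormalizedData, sigma_a=None):
    """Map-coefficient sets for docking.

    The centroid set D_obs * E_mean is the expected true sharpened
    coefficient; synthesis minimizes the error from the true sharpened map.
    The likelihood-weighted set 2 D_obs sigma_A / (1 - (D_obs sigma_A)^2)
    * E_mean makes the map whose correlation with a sharpened model map is
    proportional to the LLG target.
    """
    centroid = norm.terms.with_f(norm.d_obs * norm.e_mean)
    if sigma_a is None:
        raise ValueError("sigma_a field required for the likelihood-weighted "
                         "coefficient set")
    x = np.clip(norm.d_obs * np.asarray(sigma_a, dtype=float), 0.0, 1 - 1e-9)
    weight = 2.0 * x / (1.0 - x ** 2)
    likelihood = norm.terms.with_f(weight * norm.e_mean)
    return centroid, likelihood


# ---------------------------------------------------------------------------
# End-to-end analysis pipeline

@dataclasses.dataclass
class HalfMapAnalysis:
    """Everything `prepare-map` derives from one half-map pair."""

    terms1: FourierTermSet
    terms2: FourierTermSet
    terms_mean: FourierTermSet
    variances: VarianceEstimates
    signal_model: SignalModel
    sigma_s_model: np.ndarray
    sigma_s: np.ndarray          # hybrid, floored
    normalized: NormalizedData
    neighbourhood_radius: int

    def shell_table(self, bins: int = 20) -> pd.DataFrame:
        s = self.terms_mean.s
        order = np.argsort(s, kind="stable")
        rows = []
        for idx in np.array_split(order, bins):
            f1, f2 = self.terms1.f[idx], self.terms2.f[idx]
            num = np.sum((f1 * np.conj(f2)).real)
            den = np.sqrt(np.sum(np.abs(f1) ** 2) * np.sum(np.abs(f2) ** 2))
            rows.append({
                "s_min": float(s[idx].min()),
                "s_max": float(s[idx].max()),
                "d_min": float(1.0 / s[idx].max()),
                "n_terms": int(len(idx)),
                "sigma_s": float(self.sigma_s[idx].mean()),
                "sigma_e": float(self.variances.sigma_e[idx].mean()),
                "fsc": float(num / den) if den > 0 else 0.0,
                "d_obs": float(self.normalized.d_obs[idx].mean()),
                "mean_e2": float((np.abs(self.normalized.e_mean[idx]) ** 2)
                                 .mean()),
            })
        return pd.DataFrame(rows)

    def axis_profiles(self, bins: int = 12,
                      half_angle_deg: float = 25.0) -> pd.DataFrame:
        """Signal/noise power along cones about the x, y and z axes."""
        hkl = self.terms_mean.hkl.astype(float)
        s = self.terms_mean.s
        svec = hkl / self.terms_mean.cell[None, :]
        u = svec / np.maximum(s, 1e-12)[:, None]
        cos_min = np.cos(np.deg2rad(half_angle_deg))
        rows = []
        edges = np.quantile(s, np.linspace(0, 1, bins + 1))
        for axis, name in enumerate("xyz"):
            on_axis = np.abs(u[:, axis]) >= cos_min
            for lo, hi in zip(edges[:-1], edges[1:]):
                sel = on_axis & (s >= lo) & (s < hi)
                if sel.sum() < 5:
                    continue
                rows.append({
                    "axis": name,
                    "s_centre": float(0.5 * (lo + hi)),
                    "n_terms": int(sel.sum()),
                    "sigma_s": float(self.sigma_s[sel].mean()),
                    "sigma_e": float(self.variances.sigma_e[sel].mean()),
                })
        return pd.DataFrame(rows)


def check_unfiltered(F1: np.ndarray, F2: np.ndarray, s: np.ndarray,
                     bins: int = 10, rel_tol: float = 1e-6) -> bool:
    """Warn when any shell of the half-map difference collapses to ~zero.

    A vanishing difference power is the signature of filtered or duplicated
    half-maps, which invalidate the error model (it needs the raw,
    unfiltered, unmasked reconstructions).
    """
    diff = np.abs(F1 - F2) ** 2
    power = 0.5 * (np.abs(F1) ** 2 + np.abs(F2) ** 2)
    order = np.argsort(s, kind="stable")
    ok = True
    for idx in np.array_split(order, bins):
        if power[idx].mean() > 0 and \
                diff[idx].mean() < rel_tol * power[idx].mean():
            ok = False
    if not ok:
        warnings.warn(
            "half-map difference power is ~0 in at least one resolution "
            "shell; the inputs look filtered or duplicated, and the noise "
            "model will be unreliable", UserWarning)
    return ok


def analyze_half_maps(map1: MapGrid, map2: MapGrid,
                      d_min: Optional[float] = None, bins: int = 20,
                      neighbourhood_terms: int = 100,
                      best: Optional[BestCurve] = None,
                      refine_kwargs: Optional[dict] = None) -> HalfMapAnalysis:
    """Full signal/noise analysis of a half-map pair.

    Returns local variance estimates, the refined anisotropic signal model,
    the hybrid signal power, D_obs and normalized averaged coefficients on
    the Hermitian-unique half-set up to ``d_min``.
    """
    if map1.shape != map2.shape or \
            abs(map1.voxel_size - map2.voxel_size) > 1e-6:
        raise ValueError("half-maps must share grid and voxel size")
    if d_min is None:
        d_min = 2.0 * map1.voxel_size
    shape = map1.shape
    F1 = np.fft.fftn(map1.values)
    F2 = np.fft.fftn(map2.values)
    H, K, L = _hkl_grids(shape)
    box = map1.box
    s_grid = np.sqrt((H / box[0]) ** 2 + (K / box[1]) ** 2
                     + (L / box[2]) ** 2)
    in_res = (s_grid <= 1.0 / d_min + 1e-12) & (s_grid > 0)
    half = halfset_mask(shape, include_origin=False) & in_res

    # neighbourhood radius sized to hold ~neighbourhood_terms grid points
    radius = max(2, int(np.ceil((3.0 * neighbourhood_terms
                                 / (4.0 * np.pi)) ** (1.0 / 3.0))))
    total_power = 0.5 * (np.abs(F1) ** 2 + np.abs(F2) ** 2)
    trend_total = radial_trend(total_power, s_grid, in_res)
    trend_diff = radial_trend(np.abs(F1 - F2) ** 2, s_grid, in_res)
    fields = local_variance_fields(F1, F2, in_res, radius,
                                   trend_total=trend_total,
                                   trend_diff=trend_diff)

    hkl = np.column_stack([H[half], K[half], L[half]])
    s = s_grid[half]
    order = np.argsort(s, kind="stable")
    hkl, s = hkl[order], s[order]
    h, k, l = hkl.T

    t1 = FourierTermSet(hkl, F1[h, k, l], s, box, shape)
    t2 = FourierTermSet(hkl, F2[h, k, l], s, box, shape)
    check_unfiltered(t1.f, t2.f, s)

    mean_power = 0.5 * float((np.abs(t1.f) ** 2 + np.abs(t2.f) ** 2).mean())
    floor = SIGMA_E_FLOOR_FRACTION * max(mean_power, 1e-300)
    sigma_e = np.maximum(fields["sigma_e"][h, k, l], floor)
    var = VarianceEstimates(
        sigma_s_local=fields["sigma_s"][h, k, l],
        sigma_e=sigma_e,
        cc_sphere=fields["cc"][h, k, l],
        n_neighbourhood=fields["counts"][h, k, l],
    )

    model = refine_signal_model(t1, t2, sigma_e, best=best, bins=bins,
                                **(refine_kwargs or {}))
    svec = hkl / box[None, :]
    sigma_s_model = model.predict(svec)
    sigma_s = hybrid_sigma_s(var.sigma_s_local, sigma_s_model, var.cc_sphere)

    t_mean = t1.with_f(0.5 * (t1.f + t2.f))
    # local ML estimate of Sigma_S + Sigma_E/2 == local mean of |F_mean|^2,
    # trend-corrected like the other local estimates
    fmean_power = np.abs(0.5 * (F1 + F2)) ** 2
    trend_mean = radial_trend(fmean_power, s_grid, in_res)
    mean_power_grid = local_mean_field(fmean_power / trend_mean, in_res,
                                       radius) * trend_mean
    norm_power = np.maximum(mean_power_grid[h, k, l], floor)
    norm = normalize(t_mean, sigma_s, sigma_e, norm_power=norm_power)
    return HalfMapAnalysis(terms1=t1, terms2=t2, terms_mean=t_mean,
                           variances=var, signal_model=model,
                           sigma_s_model=sigma_s_model, sigma_s=sigma_s,
                           normalized=norm, neighbourhood_radius=radius)
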