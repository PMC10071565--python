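"""Likelihood targets for docking an atomic model into prepared map data.

The single-term log-likelihood gain (LLG) compares the conditional complex
normal p(E_mean; E_C) — expected value D_obs sigma_A E_C, variance
1 - (D_obs sigma_A)^2 — with the uninformative model sigma_A = 0.  With
x = D_obs sigma_A and amplitudes/phase difference (E_m, E_c, dphi):

    LLG = -ln(1 - x^2) + [2 x E_m E_c cos(dphi) - x^2 (E_m^2 + E_c^2)]
                         / (1 - x^2)

Summed over terms this splits into a correlation term (linear in the model
phases, hence computable for every translation with one FFT), a scale term
in the amplitudes only, and a constant offset.  Orientations are scored with
the amplitude-only (Rice) version of the same likelihood, evaluated directly
on an orientation grid.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import gemmi
import numpy as np
import pandas as pd
from scipy import optimize
from scipy.ndimage import map_coordinates
from scipy.spatial.transform import Rotation
from scipy.special import i0e

from .error_model import NormalizedData
from .fourier_core import (FourierTermSet, OversamplingInfo,
                           gaussian_atom_density, shell_profile)

__all__ = [
    "AtomModel",
    "Pose",
    "ModelFourier",
    "LLGReport",
    "sigma_a",
    "model_to_efc",
    "shift_model_fourier",
    "llg_term",
    "rice_llg_term",
    "total_llg",
    "orientation_grid",
    "rotation_score",
    "translation_search_fft",
    "refine_pose",
    "dock_model",
]

X_CAP = 1.0 - 1e-9     # cap on D_obs * sigma_A before logs

# sigma_A = sqrt(f) exp(-2 pi^2 Delta^2 s^2 / 3): characteristic function of
# an isotropic 3-D Gaussian coordinate error with rms radial error Delta
# (equivalently an error B-factor B = 8 pi^2 Delta^2 / 3).
SIGMA_A_SLOPE = 2.0 * np.pi ** 2 / 3.0


def sigma_a(f: float, delta: float, s) -> np.ndarray:
    """Model-quality correlation from completeness f and rms error Delta."""
    if not 0 < f <= 1:
        raise ValueError("completeness f must be in (0, 1]")
    if delta < 0:
        raise ValueError("rms coordinate error must be non-negative")
    s = np.asarray(s, dtype=float)
    return np.sqrt(f) * np.exp(-SIGMA_A_SLOPE * delta ** 2 * s ** 2)


# ---------------------------------------------------------------------------
# Atomic models and poses

@dataclasses.dataclass
class AtomModel:
    """Point-atom model rendered as isotropic Gaussians.

    ``weights`` are per-atom scattering weights (electron counts for real
    models, unity for synthetic pseudo-atoms); ``width`` is the Gaussian
    sigma in Angstrom.
    """

    coords: np.ndarray
    weights: np.ndarray = None
    width: float = 1.2

    def __post_init__(self):
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.weights is None:
            self.weights = np.ones(len(self.coords))
        self.weights = np.broadcast_to(
            np.asarray(self.weights, dtype=float), (len(self.coords),))

    @classmethod
    def from_file(cls, path, width: float = 1.2) -> "AtomModel":
        """Read a PDB or mmCIF model; weights are element atomic numbers."""
        st = gemmi.read_structure(str(path))
        coords, weights = [], []
        for model in st:
            for chain in model:
                for res in chain:
                    for atom in res:
                        coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                        weights.append(max(atom.element.atomic_number, 1))
            break
        return cls(np.array(coords), np.array(weights, dtype=float), width)

    @property
    def com(self) -> np.ndarray:
        return np.average(self.coords, axis=0, weights=self.weights)

    @property
    def radius(self) -> float:
        return float(np.max(np.linalg.norm(self.coords - self.com, axis=1)))


@dataclasses.dataclass
class Pose:
    """Rigid-body pose: perturbation rotations about the model COM,
    a translation and a cell scale factor.

    Rotation angles (degrees) are applied sequentially about the fixed x, y
    and z axes through the centre of mass — locally near-orthogonal
    parameters, unlike Euler angles.
    """

    rot_deg: np.ndarray = dataclasses.field(
        default_factory=lambda: np.zeros(3))
    translation: np.ndarray = dataclasses.field(
        default_factory=lambda: np.zeros(3))
    scale: float = 1.0

    def __post_init__(self):
        self.rot_deg = np.asarray(self.rot_deg, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not 0.5 < self.scale < 2.0:
            raise ValueError("cell scale factor out of sane range")

    @property
    def rotation(self) -> Rotation:
        return Rotation.from_euler("xyz", self.rot_deg, degrees=True)

    def apply(self, coords: np.ndarray, com: np.ndarray) -> np.ndarray:
        moved = self.rotation.apply(coords - com) + com + self.translation
        return self.scale * moved

    def compose_rotation(self, base: Rotation) -> "Pose":
        """Pose whose rotation is this perturbation applied after ``base``."""
        combined = self.rotation * base
        return Pose(combined.as_euler("xyz", degrees=True),
                    self.translation.copy(), self.scale)


@dataclasses.dataclass
class ModelFourier:
    """Normalized model coefficients with their sigma_A quality curve."""

    terms: FourierTermSet        # bookkeeping (hkl, s) shared with the data
    e_c: np.ndarray              # normalized complex model coefficients
    sigma_a: np.ndarray
    f: float                     # completeness fraction
    delta: float                 # rms radial coordinate error, Angstrom

    def phase_difference(self, e_mean: np.ndarray) -> np.ndarray:
        return np.angle(e_mean * np.conj(self.e_c))


def _shell_indices(s: np.ndarray, bins: int = 20):
    order = np.argsort(s, kind="stable")
    idx = np.empty(len(s), dtype=int)
    for b, chunk in enumerate(np.array_split(order, bins)):
        idx[chunk] = b
    return idx


def _normalize_smooth(f: np.ndarray, s: np.ndarray, bins: int = 40):
    """Normalize coefficients to unit mean-square power with a smooth
    per-term spectrum (interpolated log shell power), so the normalizer has
    no staircase jumps — the likelihood amplifies any per-term mismatch by
    1/(1 - x^2), which is large wherever the data are good."""
    centres, means = shell_profile(s, np.abs(f) ** 2, bins=bins)
    log_power = np.interp(s, centres, np.log(means))
    return f / np.exp(0.5 * log_power)


def model_to_efc(model: AtomModel, terms: FourierTermSet,
                 pose: Optional[Pose] = None, f: float = 1.0,
                 delta: float = 1.0, bins: int = 20) -> ModelFourier:
    """Normalized model transform E_C on the data's hkl set, under a pose.

    The posed model is rendered as Gaussian atoms on the data grid and
    transformed by FFT (exact within the grid sampling); coefficients are
    normalized to unit mean square power in equal-count resolution shells.
    """
    coords = model.coords
    if pose is not None:
        coords = pose.apply(coords, model.com)
    voxel = float(terms.cell[0] / terms.grid_shape[0])
    rho = gaussian_atom_density(coords, model.weights, model.width,
                                terms.grid_shape, voxel)
    F = np.fft.fftn(rho)
    h, k, l = terms.hkl.T
    fc = F[h, k, l]
    e_c = _normalize_smooth(fc, terms.s)
    return ModelFourier(terms=terms, e_c=e_c,
                        sigma_a=sigma_a(f, delta, terms.s), f=f, delta=delta)


def shift_model_fourier(mf: ModelFourier, translation) -> ModelFourier:
    """Apply the Fourier shift theorem: translation by t multiplies each
    coefficient by exp(-2 pi i h . t / box)."""
    t_frac = np.asarray(translation, dtype=float) / mf.terms.cell
    phase = np.exp(-2j * np.pi * (mf.terms.hkl @ t_frac))
    return ModelFourier(mf.terms, mf.e_c * phase, mf.sigma_a, mf.f, mf.delta)


# ---------------------------------------------------------------------------
# LLG

def llg_term(e_mean_amp, e_c_amp, delta_phi, d_obs, sigma_a_val):
    """Single-term log-likelihood gain over the uninformative model."""
    x = np.asarray(d_obs, float) * np.asarray(sigma_a_val, float)
    if np.any(x >= 1.0) or np.any(x < 0):
        raise ValueError("D_obs * sigma_A must lie in [0, 1)")
    em = np.asarray(e_mean_amp, float)
    ec = np.asarray(e_c_amp, float)
    one = 1.0 - x ** 2
    return (-np.log(one)
            + (2.0 * x * em * ec * np.cos(delta_phi)
               - x ** 2 * (em ** 2 + ec ** 2)) / one)


def rice_llg_term(e_mean_amp, e_c_amp, d_obs, sigma_a_val):
    """Amplitude-only LLG (phases unknown): the Rice-likelihood gain used by
    the rotation target; D_obs plays the crystallographic LLGI role."""
    x = np.clip(np.asarray(d_obs, float) * np.asarray(sigma_a_val, float),
                0.0, X_CAP)
    em = np.asarray(e_mean_amp, float)
    ec = np.asarray(e_c_amp, float)
    one = 1.0 - x ** 2
    z = 2.0 * x * em * ec / one
    # ln I0(z) = ln i0e(z) + |z|, numerically stable for large z
    return (-np.log(one) - x ** 2 * (em ** 2 + ec ** 2) / one
            + np.log(i0e(z)) + np.abs(z))


@dataclasses.dataclass
class LLGReport:
    """Total LLG with its correlation/scale/offset decomposition."""

    total: float
    correction_factor: float
    per_term: np.ndarray
    correlation: float           # 2x/(1-x^2) E_m E_c cos(dphi) part
    scale_term: float            # -x^2/(1-x^2) (E_m^2 + E_c^2) part
    offset: float                # -ln(1-x^2) part
    shell_table: Optional[pd.DataFrame] = None

    @property
    def decomposition_total(self) -> float:
        return self.correction_factor * (self.correlation + self.scale_term
                                         + self.offset)


def total_llg(norm: NormalizedData, mf: ModelFourier,
              over: OversamplingInfo, shells: int = 0) -> LLGReport:
    """Oversampling-corrected total LLG with its Eq-form cross-check.

    The sum of per-term LLG values and the correlation + scale + offset
    decomposition are computed through different expressions and verified to
    agree to 1e-8 relative on every call.
    """
    if len(norm) != len(mf.e_c) or \
            not np.array_equal(norm.terms.hkl, mf.terms.hkl):
        raise ValueError("data and model term sets are not aligned on hkl")
    x = np.clip(norm.d_obs * mf.sigma_a, 0.0, X_CAP)
    em = np.abs(norm.e_mean)
    ec = np.abs(mf.e_c)
    dphi = mf.phase_difference(norm.e_mean)
    per_term = llg_term(em, ec, dphi, norm.d_obs,
                        np.minimum(mf.sigma_a, X_CAP / np.maximum(
                            norm.d_obs, 1e-300)))
    one = 1.0 - x ** 2
    w = 2.0 * x / one
    correlation = float(np.sum((w * norm.e_mean * np.conj(mf.e_c)).real))
    scale_term = float(-np.sum(x ** 2 / one * (em ** 2 + ec ** 2)))
    offset = float(-np.sum(np.log(one)))
    total = over.factor * float(per_term.sum())
    decomp = over.factor * (correlation + scale_term + offset)
    ref = max(abs(total), abs(decomp), 1.0)
    if abs(total - decomp) > 1e-8 * ref:
        raise AssertionError(
            f"LLG decomposition mismatch: {total} vs {decomp}")
    table = None
    if shells:
        idx = _shell_indices(norm.terms.s, shells)
        rows = []
        for b in range(shells):
            sel = idx == b
            rows.append({"shell": b,
                         "s_max": float(norm.terms.s[sel].max()),
                         "llg": over.factor * float(per_term[sel].sum())})
        table = pd.DataFrame(rows)
    return LLGReport(total=total, correction_factor=over.factor,
                     per_term=over.factor * per_term,
                     correlation=correlation, scale_term=scale_term,
                     offset=offset, shell_table=table)


# ---------------------------------------------------------------------------
# Rotation search

_SF_PHI = np.sqrt(2.0)
_SF_PSI = 1.533751168755204288118041


def orientation_grid(step_deg: Optional[float] = None,
                     n: Optional[int] = None,
                     d_min: Optional[float] = None,
                     model_radius: Optional[float] = None) -> Rotation:
    """Quasi-uniform SO(3) sample (super-Fibonacci spiral).

    Either give ``n`` directly, or a target angular step (``step_deg``), or
    let the step default to 2 asin(d_min / (4 R)) for model radius R.
    """
    if n is None:
        if step_deg is None:
            if d_min is None or model_radius is None:
                raise ValueError("need n, step_deg, or d_min+model_radius")
            step_deg = np.rad2deg(
                2.0 * np.arcsin(min(d_min / (4.0 * model_radius), 1.0)))
        theta = np.deg2rad(step_deg)
        n = max(1, int(np.ceil(48.0 * np.pi / theta ** 3)))
    i = np.arange(n) + 0.5
    t = i / n
    r = np.sqrt(t)
    big_r = np.sqrt(1.0 - t)
    alpha = 2.0 * np.pi * i / _SF_PHI
    beta = 2.0 * np.pi * i / _SF_PSI
    quats = np.column_stack([r * np.sin(alpha), r * np.cos(alpha),
                             big_r * np.sin(beta), big_r * np.cos(beta)])
    return Rotation.from_quat(quats)


def _rotated_amplitudes_interp(amp_grid_shifted: np.ndarray,
                               hkl: np.ndarray, rot: Rotation) -> np.ndarray:
    """Trilinear lookup of |F_model| at rotated hkl (cubic box)."""
    n = amp_grid_shifted.shape[0]
    centre = n // 2
    rotated = rot.inv().apply(hkl.astype(float)) + centre
    return map_coordinates(amp_grid_shifted, rotated.T, order=1,
                           mode="constant", cval=0.0)


def rotation_score(norm: NormalizedData, model: AtomModel,
                   orientations: Rotation, over: OversamplingInfo,
                   f: float = 1.0, delta: float = 1.0,
                   method: str = "interp", rescore_top: int = 10,
                   bins: int = 20) -> pd.DataFrame:
    """Score orientations with the amplitude-only likelihood target.

    ``interp`` pre-ranks all orientations by interpolating the rotated
    model amplitude spectrum (amplitudes only — exactly the quantity the
    target needs), then rescores the best ``rescore_top`` by exact
    Gaussian-atom synthesis.  ``exact`` synthesizes every orientation.
    Scores are invariant to model translation by construction.
    """
    if len(orientations) == 0:
        raise ValueError("empty orientation grid")
    em = np.abs(norm.e_mean)
    sa = sigma_a(f, delta, norm.terms.s)

    def exact_score(rot: Rotation) -> float:
        pose = Pose(rot.as_euler("xyz", degrees=True))
        mf = model_to_efc(model, norm.terms, pose, f=f, delta=delta,
                          bins=bins)
        return over.factor * float(
            rice_llg_term(em, np.abs(mf.e_c), norm.d_obs, sa).sum())

    rows = []
    if method == "exact":
        for i in range(len(orientations)):
            rows.append((i, exact_score(orientations[i]), True))
    else:
        voxel = float(norm.terms.cell[0] / norm.terms.grid_shape[0])
        centred = model.coords - model.com + norm.terms.cell / 2.0
        rho = gaussian_atom_density(centred, model.weights, model.width,
                                    norm.terms.grid_shape, voxel)
        amp = np.fft.fftshift(np.abs(np.fft.fftn(rho)))
        for i in range(len(orientations)):
            ac = _rotated_amplitudes_interp(amp, norm.terms.hkl,
                                            orientations[i])
            ec = np.abs(_normalize_smooth(ac.astype(complex), norm.terms.s))
            score = over.factor * float(
                rice_llg_term(em, ec, norm.d_obs, sa).sum())
            rows.append((i, score, False))
        rows.sort(key=lambda r: -r[1])
        rescored = []
        for i, _, _ in rows[:max(rescore_top, 1)]:
            rescored.append((i, exact_score(orientations[i]), True))
        kept = {i for i, _, _ in rescored}
        rows = rescored + [r for r in rows if r[0] not in kept]
    df = pd.DataFrame(rows, columns=["orientation_index", "llg_rot", "exact"])
    df = df.sort_values("llg_rot", ascending=False,
                        kind="stable").reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# Translation search

def translation_search_fft(norm: NormalizedData, mf: ModelFourier,
                           over: OversamplingInfo) -> np.ndarray:
    """Exact LLG for every grid translation of an oriented model, one FFT.

    Only the correlation part of the LLG depends on the translation (the
    amplitude spectrum is shift-invariant), so the full translation grid is
    the inverse FFT of the weighted data-model coefficient product plus a
    constant.  Grid index (i, j, k) is a translation of (i, j, k) voxels.
    """
    x = np.clip(norm.d_obs * mf.sigma_a, 0.0, X_CAP)
    one = 1.0 - x ** 2
    em = np.abs(norm.e_mean)
    ec = np.abs(mf.e_c)
    const = float(np.sum(-np.log(one) - x ** 2 / one * (em ** 2 + ec ** 2)))
    g = (2.0 * x / one) * norm.e_mean * np.conj(mf.e_c)
    grid = np.zeros(norm.terms.grid_shape, dtype=np.complex128)
    h, k, l = norm.terms.hkl.T
    grid[h, k, l] = g
    grid[-h, -k, -l] = np.conj(g)
    nvox = np.prod(norm.terms.grid_shape)
    corr = 0.5 * nvox * np.fft.ifftn(grid).real
    return over.factor * (const + corr)


# ---------------------------------------------------------------------------
# Rigid-body refinement

def refine_pose(pose0: Pose, norm: NormalizedData, model: AtomModel,
                over: OversamplingInfo, f: float = 1.0,
                delta0: float = 1.0, refine_delta: bool = False,
                refine_scale: bool = False,
                delta_bounds=(0.1, 3.0), scale_bounds=(0.9, 1.1),
                rot_window: float = 30.0, trans_window: float = 10.0,
                max_iter: int = 200):
    """Maximize the LLG over rigid-body parameters from a starting pose.

    Parameters are three perturbation rotations about the model COM
    (degrees), three translations (Angstrom), optionally the sigma_A error
    Delta and the cell scale factor.  Quasi-Newton (L-BFGS-B) with numeric
    gradients; the returned path holds the accepted (monotone) LLG values.

    Returns (pose, delta, llg_path, final_llg).
    """
    base_rot = pose0.rotation
    base_t = pose0.translation.copy()
    p0 = [0.0, 0.0, 0.0, 0.0, 0.0, 0.0]
    lb = [-rot_window] * 3 + [-trans_window] * 3
    ub = [rot_window] * 3 + [trans_window] * 3
    if refine_delta:
        p0.append(delta0)
        lb.append(delta_bounds[0])
        ub.append(delta_bounds[1])
    if refine_scale:
        p0.append((pose0.scale - 1.0) * 100.0)
        lb.append((scale_bounds[0] - 1.0) * 100.0)
        ub.append((scale_bounds[1] - 1.0) * 100.0)

    path = []
    best = {"llg": -np.inf, "p": np.asarray(p0, dtype=float)}

    def build_pose(p):
        pert = Rotation.from_euler("xyz", p[:3], degrees=True)
        rot = (pert * base_rot).as_euler("xyz", degrees=True)
        scale = pose0.scale
        if refine_scale:
            scale = 1.0 + p[-1] / 100.0
        return Pose(rot, base_t + p[3:6], scale)

    def objective(p):
        pose = build_pose(p)
        delta = p[6] if refine_delta else delta0
        try:
            mf = model_to_efc(model, norm.terms, pose, f=f, delta=delta)
        except ValueError:          # atoms pushed outside the box
            return 1e30
        llg = total_llg(norm, mf, over).total
        if llg > best["llg"]:
            best["llg"] = llg
            best["p"] = np.array(p, dtype=float)
        return -llg

    def callback(p):
        if not path or best["llg"] >= path[-1]:
            path.append(best["llg"])

    path.append(-objective(np.asarray(p0)))
    optimize.minimize(
        objective, np.asarray(p0), method="L-BFGS-B",
        bounds=list(zip(lb, ub)), callback=callback,
        options={"maxiter": max_iter, "eps": 1e-3, "ftol": 1e-12,
                 "gtol": 1e-8})
    path.append(best["llg"])
    pose = build_pose(best["p"])
    delta = float(best["p"][6]) if refine_delta else delta0
    return pose, delta, np.array(path), float(best["llg"])


# ---------------------------------------------------------------------------
# Full docking pipeline: rotation search -> translation -> refinement

def dock_model(norm: NormalizedData, model: AtomModel,
               over: OversamplingInfo, f: float = 1.0, delta: float = 1.0,
               orientations: Optional[Rotation] = None,
               n_orientations: int = 2000, top_orientations: int = 10,
               refine_delta: bool = False, refine_scale: bool = False,
               low_res_factor: float = 2.0,
               null_threshold_z: float = 6.0) -> dict:
    """End-to-end docking of one model into prepared map data.

    Orientation scan (amplitude-only likelihood) -> FFT translation search
    for the leading orientations -> rigid-body refinement, first against a
    resolution-limited subset (wider convergence basin), then at full
    resolution.  A solution is flagged significant when its translation
    peak stands out from the grid by more than ``null_threshold_z``
    standard deviations; the expected maximum of the ~n_voxel null scores
    is itself about sqrt(2 ln n) ~ 4.5 sigma, hence the margin.
    """
    if orientations is None:
        orientations = orientation_grid(n=n_orientations)
    ranked = rotation_score(norm, model, orientations, over, f=f,
                            delta=delta, rescore_top=top_orientations)
    voxel = float(norm.terms.cell[0] / norm.terms.grid_shape[0])
    s_low = norm.terms.s.max() / low_res_factor
    low = norm.select(norm.terms.s <= s_low)

    candidates = []
    for _, row in ranked.head(top_orientations).iterrows():
        rot = orientations[int(row.orientation_index)]
        pose_r = Pose(rot.as_euler("xyz", degrees=True))
        mf = model_to_efc(model, norm.terms, pose_r, f=f, delta=delta)
        grid = translation_search_fft(norm, mf, over)
        idx = np.unravel_index(np.argmax(grid), grid.shape)
        shift = np.array([np.fft.fftfreq(n, 1.0 / n)[i]
                          for n, i in zip(grid.shape, idx)])
        t = shift * voxel
        peak_z = float((grid.max() - grid.mean()) / max(grid.std(), 1e-300))
        pose_t = Pose(pose_r.rot_deg, t)
        pose_lo, _, _, _ = refine_pose(pose_t, low, model,
                                       over, f=f, delta0=delta,
                                       rot_window=25.0, trans_window=1.5 * voxel + 2.0)
        mf_hi = model_to_efc(model, norm.terms, pose_lo, f=f, delta=delta)
        llg_hi = total_llg(norm, mf_hi, over).total
        candidates.append((llg_hi, pose_lo, float(grid.max()), peak_z))

    candidates.sort(key=lambda c: -c[0])
    _, pose_best, tf_peak, peak_z = candidates[0]
    pose, delta_ref, path, llg = refine_pose(
        pose_best, norm, model, over, f=f, delta0=delta,
        refine_delta=refine_delta, refine_scale=refine_scale,
        rot_window=15.0, trans_window=5.0)
    return {
        "pose": pose,
        "llg": llg,
        "delta": delta_ref,
        "llg_path": path,
        "rotation_table": ranked,
        "translation_peak": tf_peak,
        "peak_z": peak_z,
        "significant": bool(peak_z > null_threshold_z),
    }
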