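"""Expected-LLG planning scores and information-gain measures.

With x = D_obs * sigma_A, the closed forms are

    eLLG_tra per term = -ln(1 - x^2)
    eLLG_rot per term = -ln(1 - x^4) / 2
    D_KL    per term  = -ln(1 - D_obs^2)   (a perfect model: sigma_A = 1)

The translation form is the expectation of the phased LLG over the
conditional distribution of the model coefficient given the data (the
cross term in E_mean^2 has zero mean and the squared-amplitude correlations
are dropped); the rotation form is the amplitude-only analogue with the
exact quartic small-x limit x^4/2.  At x = 0.01 their ratio is ~20 000 —
the measure of how much phase information enhances the translation search.

The Fourier shell information of van Heel & Schatz,
FSI = K log2[(1 + FSC)/(1 - FSC)], equals K times the per-term D_KL in bits
after substituting the Rosenthal-Henderson relation
D_obs = FSC_ref = sqrt(2 FSC / (1 + FSC)).
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd

from .error_model import NormalizedData
from .fourier_core import FourierTermSet, OversamplingInfo
from .likelihood import sigma_a as sigma_a_curve

__all__ = [
    "InfoReport",
    "ellg_rot_term",
    "ellg_tra_term",
    "dkl_term",
    "dobs_from_fsc",
    "fsc_from_dobs",
    "fsi_shell",
    "filter_by_information",
    "make_info_report",
]

D_OBS_CAP = 1.0 - 1e-9
LN2 = np.log(2.0)
DEFAULT_THRESHOLD_BITS = 0.01


def _checked_x(d_obs, sigma_a):
    x = np.asarray(d_obs, dtype=float) * np.asarray(sigma_a, dtype=float)
    if np.any(x < 0) or np.any(x >= 1.0):
        raise ValueError("D_obs * sigma_A must lie in [0, 1)")
    return x


def ellg_rot_term(d_obs, sigma_a):
    """Expected rotation-function LLG per term (amplitude-only, P1).

    Scales as (D_obs sigma_A)^4 / 2 for weak signal — the quartic penalty
    that makes rotation searches so much harder than translation searches.
    """
    x = _checked_x(d_obs, sigma_a)
    return -0.5 * np.log1p(-x ** 4)


def ellg_tra_term(d_obs, sigma_a):
    """Expected translation/refinement LLG per term (phased target)."""
    x = _checked_x(d_obs, sigma_a)
    return -np.log1p(-x ** 2)


def dkl_term(d_obs):
    """Kullback-Leibler information gained about one true Fourier term.

    Equals the expected LLG of a perfect model (sigma_A = 1).  D_obs is
    capped at 1 - 1e-9; D_obs = 1 would be infinite information.
    Returns (nats, bits).
    """
    d = np.asarray(d_obs, dtype=float)
    if np.any(d < 0) or np.any(d > 1.0):
        raise ValueError("d_obs must lie in [0, 1]")
    d = np.minimum(d, D_OBS_CAP)
    nats = -np.log1p(-d ** 2)
    return nats, nats / LN2


def dobs_from_fsc(fsc):
    """Rosenthal-Henderson: FSC_ref (= per-term D_obs) from half-map FSC."""
    fsc = np.clip(np.asarray(fsc, dtype=float), 0.0, None)
    return np.sqrt(2.0 * fsc / (1.0 + fsc))


def fsc_from_dobs(d_obs):
    """Inverse Rosenthal-Henderson relation: FSC = D_obs^2/(2 - D_obs^2)."""
    d2 = np.asarray(d_obs, dtype=float) ** 2
    return d2 / (2.0 - d2)


def fsi_shell(fsc, k):
    """Fourier shell information in bits: K log2[(1 + FSC)/(1 - FSC)].

    K is the effective number of independent terms in the shell.  After the
    Rosenthal-Henderson substitution this equals K * dkl_term(D_obs) in
    bits, exactly.
    """
    fsc = np.asarray(fsc, dtype=float)
    if np.any(fsc >= 1.0):
        raise ValueError("FSC must be below 1")
    if np.any(np.asarray(k) < 1):
        raise ValueError("K must be at least 1")
    fsc = np.clip(fsc, 0.0, None)
    return np.asarray(k, dtype=float) * np.log2((1.0 + fsc) / (1.0 - fsc))


def filter_by_information(terms: FourierTermSet, d_obs_field,
                          threshold_bits: float = DEFAULT_THRESHOLD_BITS,
                          over: Optional[OversamplingInfo] = None,
                          correct_before_threshold: bool = True):
    """Drop Fourier terms carrying almost no information.

    Terms whose information gain (after the oversampling correction, by
    default) falls below ``threshold_bits`` are discarded — they cannot
    influence the likelihood materially but cost time.  Returns the
    surviving subset and a small report dict.
    """
    d = np.asarray(d_obs_field, dtype=float)
    _, bits = dkl_term(d)
    factor = over.factor if over is not None else 1.0
    effective = bits * factor if correct_before_threshold else bits
    keep = effective >= threshold_bits
    report = {
        "n_input": int(len(d)),
        "n_kept": int(keep.sum()),
        "n_discarded": int((~keep).sum()),
        "discarded_bits": float((bits * factor)[~keep].sum()),
        "kept_bits": float((bits * factor)[keep].sum()),
        "threshold_bits": float(threshold_bits),
    }
    return terms.select(keep), keep, report


@dataclasses.dataclass
class InfoReport:
    """Per-term and per-shell planning scores for a prepared data set."""

    per_term_ellg_rot: np.ndarray
    per_term_ellg_tra: np.ndarray
    per_term_dkl_nats: np.ndarray
    per_term_dkl_bits: np.ndarray
    shell_table: pd.DataFrame
    total_ellg_rot: float
    total_ellg_tra: float
    total_bits: float
    correction_factor: float


def make_info_report(norm: NormalizedData, over: OversamplingInfo,
                     f: float = 1.0, delta: float = 1.0,
                     bins: int = 20) -> InfoReport:
    """eLLG and information summary over resolution shells.

    The effective independent term count K per shell is the raw count times
    the oversampling factor; all totals carry the same correction.
    """
    s = norm.terms.s
    sa = sigma_a_curve(f, delta, s)
    x = np.minimum(norm.d_obs * sa, D_OBS_CAP)
    rot = -0.5 * np.log1p(-x ** 4)
    tra = -np.log1p(-x ** 2)
    nats, bits = dkl_term(norm.d_obs)
    order = np.argsort(s, kind="stable")
    rows = []
    for idx in np.array_split(order, bins):
        d_mean = float(norm.d_obs[idx].mean())
        k_eff = max(len(idx) * over.factor, 1.0)
        rows.append({
            "s_min": float(s[idx].min()),
            "s_max": float(s[idx].max()),
            "d_min": float(1.0 / s[idx].max()),
            "n_terms": int(len(idx)),
            "k_eff": float(k_eff),
            "fsc": float(fsc_from_dobs(d_mean)),
            "d_obs": d_mean,
            "ellg_rot": float(over.factor * rot[idx].sum()),
            "ellg_tra": float(over.factor * tra[idx].sum()),
            "bits": float(over.factor * bits[idx].sum()),
        })
    return InfoReport(
        per_term_ellg_rot=rot, per_term_ellg_tra=tra,
        per_term_dkl_nats=nats, per_term_dkl_bits=bits,
        shell_table=pd.DataFrame(rows),
        total_ellg_rot=float(over.factor * rot.sum()),
        total_ellg_tra=float(over.factor * tra.sum()),
        total_bits=float(over.factor * bits.sum()),
        correction_factor=over.factor,
    )
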