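"""Inverse Mills ratio and the probit generalized residual.

The control function inserted into the second stage is the probit score
residual

    m_i = MHM_i * mu(x_i'a) - (1 - MHM_i) * mu(-x_i'a),   mu(z) = phi(z)/Phi(z)

whose sample mean is exactly zero at the first-stage MLE when an intercept
is present (it is the intercept's score equation).  mu is evaluated through
the log-CDF so it neither overflows nor underflows anywhere in the usable
double range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = ["mills_ratio", "generalized_residual", "GeneralizedResiduals"]

#: Indices beyond this magnitude are clamped; mu(-40) ~ 40.025 and
#: mu(40) ~ 1e-349 underflows to 0, so nothing of statistical relevance
#: lives outside the window.
INDEX_CLAMP = 40.0


def mills_ratio(z):
    """Inverse Mills ratio mu(z) = phi(z) / Phi(z), stable for |z| <= 40.

    Computed as exp(log phi(z) - log Phi(z)); strictly positive and
    strictly decreasing.  Scalar in, scalar out.
    """
    z = np.asarray(z, dtype=float)
    out = np.exp(norm.logpdf(z) - norm.logcdf(z))
    return out if out.ndim else float(out)


@dataclass
class GeneralizedResiduals:
    """Per-row generalized residuals plus the first-stage they came from."""

    m_hat: np.ndarray
    source_fit: object | None = None

    def mean(self) -> float:
        return float(np.mean(self.m_hat))


def generalized_residual(mhm, index, source_fit=None) -> GeneralizedResiduals:
    """Probit generalized residual per row.

    Parameters
    ----------
    mhm:
        Binary treatment indicator (0/1), no missing values: imputation
        must have run before this stage.
    index:
        First-stage linear index x'a per row.
    """
    mhm = np.asarray(mhm, dtype=float)
    index = np.asarray(index, dtype=float)
    if mhm.shape != index.shape:
        raise ValueError("mhm and index must have equal length")
    if np.isnan(mhm).any():
        raise ValueError("mhm contains missing values; run imputation first")
    if not np.isin(mhm, (0.0, 1.0)).all():
        raise ValueError("mhm must be binary 0/1")
    big = np.abs(index) > INDEX_CLAMP
    if big.any():
        warnings.warn(f"clamping {int(big.sum())} first-stage indices "
                      f"with |z| > {INDEX_CLAMP}")
        index = np.clip(index, -INDEX_CLAMP, INDEX_CLAMP)
    m_hat = mhm * mills_ratio(index) - (1.0 - mhm) * mills_ratio(-index)
    return GeneralizedResiduals(m_hat=m_hat, source_fit=source_fit)
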