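"""Shared least-squares fit reporting.

Both the interval-model and Boltzmann fitters report point estimates with
asymptotic 95% confidence intervals derived from the Jacobian at the
optimum: cov = s² (JᵀJ)⁻¹ with s² = RSS/(n − k), and a Student-t critical
value with n − k degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _st


@dataclass(frozen=True)
class FitResult:
    """Outcome of a nonlinear least-squares fit.

    Attributes
    ----------
    params : object
        Fitted parameter container (model specific).
    ci95 : dict
        Per-parameter 95% confidence interval, name -> (low, high).
    rss : float
        Residual sum of squares at the optimum.
    converged : bool
        Whether the optimizer reported success and the solution is usable.
    n : int
        Number of data points fitted.
    """

    params: object
    ci95: dict = field(default_factory=dict)
    rss: float = float("nan")
    converged: bool = False
    n: int = 0


def asymptotic_ci95(theta: np.ndarray, jac: np.ndarray, rss: float, n: int) -> np.ndarray:
    """Half-widths of the asymptotic 95% CI for each parameter.

    Returns an array of half-widths; callers build (theta - hw, theta + hw).
    A singular JᵀJ (flat directions, e.g. a degenerate mixture ridge) yields
    infinite half-widths for the affected parameters via the pseudo-inverse.
    """
    k = theta.size
    dof = max(n - k, 1)
    s2 = rss / dof
    jtj = jac.T @ jac
    try:
        cov = s2 * np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        cov = s2 * np.linalg.pinv(jtj)
    var = np.clip(np.diag(cov), 0.0, np.inf)
    tcrit = _st.t.ppf(0.975, dof)
    return tcrit * np.sqrt(var)
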