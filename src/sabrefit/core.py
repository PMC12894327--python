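"""The SABRE receptor-function response and its closed-form consequences.

SABRE (Signal Amplification, Binding affinity, and Receptor-activation
Efficacy) links the log10 molar agonist concentration ``x`` to the effect,
expressed as percent of the system maximal effect::

    E(x) = 100 * q*eps*gamma * 10^(n*x)
           / [ (q*eps*gamma - q*eps + 1) * 10^(n*x) + 10^(n*logKd) ]

where ``eps`` is receptor-activation efficacy, ``gamma`` the post-receptor
gain, ``n`` a Hill-type coefficient of post-receptor signaling, ``logKd``
the log10 equilibrium dissociation constant (molar), and ``q`` the fraction
of receptors left operable after irreversible antagonism (``q = 1`` is the
untreated control case, which reduces the equation to the control form).

Everything here is pure computation; fitting, diagnostics and simulation
build on these three functions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "SabreParams",
    "PARAM_BOUNDS",
    "sabre_response",
    "apparent_emax",
    "apparent_ec50",
]

#: Domain bounds used by validation, fitting and simulation.  They enclose
#: all plausible pharmacological values (receptor gains up to 1e6, affinities
#: from 1 M down to 1 pM) with wide margins.
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "eps": (0.0, 10.0),
    "gamma": (0.0, 1e6),
    "n": (0.0, 5.0),
    "logKd": (-12.0, 0.0),
    "q": (0.0, 1.0),
}

# exponents are clipped here before 10**e to keep the stable form finite
_EXP_CLIP = 300.0


@dataclass(frozen=True)
class SabreParams:
    """One agonist/condition's SABRE parameters.

    Attributes
    ----------
    eps : float
        Receptor-activation efficacy, dimensionless, in (0, 10].
    gamma : float
        Post-receptor gain factor, dimensionless, in (0, 1e6].
    n : float
        Hill-type coefficient of post-receptor signaling, in (0, 5].
    logKd : float
        log10 of the equilibrium dissociation constant in molar units,
        in [-12, 0].
    q : float
        Fraction of operable receptors, in [0, 1]; 1 for untreated controls.
    """

    eps: float
    gamma: float
    n: float
    logKd: float
    q: float = 1.0

    def __post_init__(self) -> None:
        validate_params(self)

    def with_q(self, q: float) -> "SabreParams":
        return replace(self, q=q)

    @property
    def denom_coefficient(self) -> float:
        """q*eps*gamma - q*eps + 1, the coefficient of 10^(n*x) in the denominator."""
        return self.q * self.eps * self.gamma - self.q * self.eps + 1.0


def validate_params(p: SabreParams) -> None:
    """Raise ``ValueError`` naming the offending field if ``p`` is out of domain."""
    if not np.isfinite(p.eps) or not (0.0 < p.eps <= PARAM_BOUNDS["eps"][1]):
        raise ValueError(f"eps must be in (0, {PARAM_BOUNDS['eps'][1]}], got {p.eps}")
    if not np.isfinite(p.gamma) or not (0.0 < p.gamma <= PARAM_BOUNDS["gamma"][1]):
        raise ValueError(
            f"gamma must be in (0, {PARAM_BOUNDS['gamma'][1]}], got {p.gamma}"
        )
    if not np.isfinite(p.n) or not (0.0 < p.n <= PARAM_BOUNDS["n"][1]):
        raise ValueError(f"n must be in (0, {PARAM_BOUNDS['n'][1]}], got {p.n}")
    lo, hi = PARAM_BOUNDS["logKd"]
    if not np.isfinite(p.logKd) or not (lo <= p.logKd <= hi):
        raise ValueError(f"logKd must be finite in [{lo}, {hi}], got {p.logKd}")
    if not np.isfinite(p.q) or not (0.0 <= p.q <= 1.0):
        raise ValueError(f"q must be in [0, 1], got {p.q}")
    # guards gamma < 1 edge cases where the denominator could change sign
    if p.denom_coefficient <= 0.0:
        raise ValueError(
            "q*eps*gamma - q*eps + 1 must be strictly positive, got "
            f"{p.denom_coefficient} (gamma={p.gamma}, eps={p.eps}, q={p.q})"
        )


def sabre_response(p: SabreParams, x):
    """Effect (% of E_max) at log10 molar concentration(s) ``x``.

    Evaluated in a numerically stable form: with ``d = n*(x - logKd)`` the
    response is ``100*q*eps*gamma / (D + 10^(-d))`` where ``D`` is the
    denominator coefficient, so neither power of ten can overflow for the
    extreme trial values a fitter explores.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite")
    d = np.clip(p.n * (x - p.logKd), -_EXP_CLIP, _EXP_CLIP)
    out = 100.0 * p.q * p.eps * p.gamma / (p.denom_coefficient + 10.0 ** (-d))
    return out if out.ndim else float(out)


def apparent_emax(p: SabreParams) -> float:
    """Supremum of the response over x, in percent of E_max.

    ``100*q*eps*gamma / (q*eps*gamma - q*eps + 1)``.  With large gain the
    apparent maximum barely drops as q falls below 1 (receptor reserve) —
    the feature that makes Furchgott-type data with high amplification hard.
    """
    validate_params(p)
    return 100.0 * p.q * p.eps * p.gamma / p.denom_coefficient


def apparent_ec50(p: SabreParams) -> float:
    """Molar concentration producing half the apparent maximal effect.

    ``10^logKd / (q*eps*gamma - q*eps + 1)^(1/n)``; with amplification the
    half-maximum point sits well to the left of Kd, and receptor loss
    (q < 1) shifts it back to the right without depressing the maximum.
    """
    validate_params(p)
    if p.q == 0.0:
        raise ValueError("apparent_ec50 undefined for q = 0 (zero response)")
    return 10.0**p.logKd / p.denom_coefficient ** (1.0 / p.n)
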