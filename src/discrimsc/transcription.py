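"""Rate law for supercoiling-dependent transcription and its fits.

The transcription rate of a promoter is a hinge-exponential function of
the bubble opening cost ``G(sigma, s)``:

    k = k0 * exp(min((dGP0*kBT - G) / kBT, 0))

where ``dGP0`` (in units of kBT) is the opening assistance contributed
by RNA polymerase.  When supercoiling makes opening cheaper than that
assistance the promoter runs at its maximal rate ``k0``; otherwise the
rate is exponentially suppressed by the residual opening cost.  Fold
changes between two supercoiling levels in the suppressed regime depend
only on the difference of opening costs, not on ``dGP0`` or ``k0``.

Three calibration fits are provided: the effective salt concentration
of the melting model (against relative expression-versus-sigma curves),
and the medium-specific supercoiling levels plus shared relaxation
magnitude of a gyrase-inhibition shock (against observed fold changes).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize

from .melting import (
    MeltingParams,
    _g_twist_grid,
    bubble_melting_cost,
    opening_cost,
    twist_relaxation_cost,
)
from .seq_io import PromoterRecord

logger = logging.getLogger("discrimsc")

__all__ = [
    "TranscriptionParams",
    "ActivationCurve",
    "SaltFit",
    "ShockFit",
    "transcription_rate",
    "log_relative_rate",
    "expression_fold_change",
    "activation_curve",
    "fit_effective_salt",
    "fit_shock_parameters",
]


@dataclass
class TranscriptionParams:
    """Parameters of the rate law.

    ``dgp0`` is the RNAP opening-assistance free energy in units of kBT
    (a single fitted value shared by all promoters, i.e. the sequence
    dependence of the RNAP-discriminator interaction is neglected);
    ``k0`` is the basal maximal rate in arbitrary units.
    """

    dgp0: float = 3.5
    k0: float = 1.0

    def __post_init__(self) -> None:
        if self.k0 <= 0:
            raise ValueError("k0 must be positive")
        if not np.isfinite(self.dgp0):
            raise ValueError("dgp0 must be finite")


@dataclass
class ActivationCurve:
    """Relative rate k/k0 of one promoter along a sigma grid."""

    promoter_id: str
    sigma_grid: np.ndarray
    rate: np.ndarray


def log_relative_rate(
    g_cost, mp: MeltingParams, tp: TranscriptionParams
) -> np.ndarray:
    """ln(k/k0) for given opening cost(s), vectorized."""
    kbt = mp.kBT
    return np.minimum((tp.dgp0 * kbt - np.asarray(g_cost, dtype=float)) / kbt, 0.0)


def transcription_rate(
    sigma: float,
    promoter: PromoterRecord,
    mp: MeltingParams,
    tp: TranscriptionParams,
) -> float:
    """Transcription rate at superhelical density ``sigma``."""
    g = opening_cost(promoter, sigma, mp)
    return float(tp.k0 * np.exp(log_relative_rate(g, mp, tp)))


def expression_fold_change(
    sigma0: float,
    dsigma: float,
    promoter: PromoterRecord,
    mp: MeltingParams,
    tp: TranscriptionParams,
) -> float:
    """Fold change ``k(sigma0 + dsigma) / k(sigma0)``.

    In the regime where the promoter is suppressed at both levels this is
    ``exp((G(sigma0) - G(sigma0 + dsigma)) / kBT)``, independent of both
    ``dgp0`` and ``k0``.
    """
    base = mp.a_nuc + bubble_melting_cost(promoter, mp)
    g0 = base + twist_relaxation_cost(sigma0, mp).g_twist
    g1 = base + twist_relaxation_cost(sigma0 + dsigma, mp).g_twist
    return float(
        np.exp(log_relative_rate(g1, mp, tp) - log_relative_rate(g0, mp, tp))
    )


def activation_curve(
    promoter: PromoterRecord,
    sigma_grid: Sequence[float],
    mp: MeltingParams,
    tp: TranscriptionParams,
) -> ActivationCurve:
    """Relative rate k/k0 along a sorted sigma grid."""
    grid = np.asarray(sigma_grid, dtype=float)
    base = mp.a_nuc + bubble_melting_cost(promoter, mp)
    g = base + _g_twist_grid(grid, mp)
    return ActivationCurve(
        promoter_id=promoter.id,
        sigma_grid=grid,
        rate=np.exp(log_relative_rate(g, mp, tp)),
    )


# ---------------------------------------------------------------------------
# calibration fits

@dataclass
class SaltFit:
    """Result of the effective-salt calibration."""

    salt: float
    residual: float
    n_points: int


@dataclass
class ShockFit:
    """Medium-specific supercoiling levels and shared relaxation magnitude."""

    sigma_rich: float
    sigma_min: float
    dsigma: float
    residual: float
    n_obs: int
    flags: list[str] = field(default_factory=list)


def _melt_1m_and_stacks(
    promoters: Sequence[PromoterRecord], mp: MeltingParams
) -> np.ndarray:
    """Per-promoter melting cost at 1 M salt (salt term enters linearly)."""
    ref = mp.with_salt(1.0)
    return np.array([bubble_melting_cost(p, ref) for p in promoters])


def fit_effective_salt(
    curves: Iterable[tuple[PromoterRecord, Sequence[float], Sequence[float]]],
    mp: MeltingParams,
    tp: TranscriptionParams,
    log10_bounds: tuple[float, float] = (-4.0, 0.0),
) -> SaltFit:
    """Least-squares calibration of the effective salt concentration.

    ``curves`` holds ``(promoter, sigma values, relative expression)``
    triples with expression normalized to a maximum of 1.  A single salt
    value shared by all promoters is searched on a log scale within
    ``log10_bounds`` (default 0.1 mM - 1 M) by bounded scalar
    minimization of the squared error between model ``k/k0`` and data.
    """
    curves = list(curves)
    proms = [c[0] for c in curves]
    sigmas = [np.asarray(c[1], dtype=float) for c in curves]
    exprs = [np.asarray(c[2], dtype=float) for c in curves]
    n_points = int(sum(len(s) for s in sigmas))
    if n_points < 3:
        raise ValueError("need at least 3 (sigma, expression) points")
    if all(np.ptp(e) == 0 for e in exprs):
        warnings.warn(
            "all expression values equal: effective salt is not identifiable",
            stacklevel=2,
        )
    melt_1m = _melt_1m_and_stacks(proms, mp)
    n_stacks = mp.n_bubble + 1
    g_twists = [_g_twist_grid(s, mp) for s in sigmas]

    def objective(log10_salt: float) -> float:
        salt_term = n_stacks * mp.m_salt * np.log(10.0**log10_salt)
        sse = 0.0
        for m1, gt, e in zip(melt_1m, g_twists, exprs):
            g = mp.a_nuc + m1 + salt_term + gt
            rate = np.exp(log_relative_rate(g, mp, tp))
            sse += float(np.sum((rate - e) ** 2))
        return sse

    res = optimize.minimize_scalar(
        objective,
        bounds=log10_bounds,
        method="bounded",
        options={"xatol": 1e-10},
    )
    return SaltFit(salt=float(10.0**res.x), residual=float(res.fun), n_points=n_points)


_SHOCK_START_SIGMAS = (-0.08, -0.05, -0.03, -0.015)
_SHOCK_START_DSIGMAS = (5e-4, 2e-3, 8e-3)


def fit_shock_parameters(
    observations: Iterable[tuple[PromoterRecord, str, float]],
    mp: MeltingParams,
    tp: TranscriptionParams,
    media: tuple[str, str] = ("rich", "minimal"),
    sigma_bounds: tuple[float, float] = (-0.1, 0.0),
    dsigma_bounds: tuple[float, float] = (1e-5, 0.05),
) -> ShockFit:
    """Fit (sigma_rich, sigma_min, dsigma) to observed shock fold changes.

    ``observations`` holds ``(promoter, medium, fold_change)`` triples
    where medium is one of ``media`` (first entry = rich).  Minimizes the
    sum of squared log-fold-change errors with a fixed multi-start
    Nelder-Mead search inside the stated bounds, so the fit is
    deterministic.  A fitted ``dsigma`` at the lower bound (no detectable
    relaxation signal) is flagged.
    """
    obs = list(observations)
    proms = [o[0] for o in obs]
    if len({p.id for p in proms}) < 2:
        raise ValueError("shock fit is not identifiable from a single promoter")
    med = np.array([o[1] for o in obs])
    unknown = set(med) - set(media)
    if unknown:
        raise ValueError(f"unknown medium labels {sorted(unknown)}")
    if set(med) != set(media):
        raise ValueError("observations must cover both growth media")
    fc = np.array([o[2] for o in obs], dtype=float)
    if np.any(fc <= 0):
        raise ValueError("fold changes must be positive")
    log_fc_obs = np.log(fc)
    is_rich = med == media[0]
    melt = np.array([bubble_melting_cost(p, mp) for p in proms])
    base = mp.a_nuc + melt

    if np.allclose(log_fc_obs, 0.0, atol=1e-12):
        # no relaxation signal at all: any plateau configuration fits
        logger.warning("shock fit: all fold changes are 1 (no signal)")
        return ShockFit(
            sigma_rich=sigma_bounds[0],
            sigma_min=sigma_bounds[0],
            dsigma=dsigma_bounds[0],
            residual=0.0,
            n_obs=len(obs),
            flags=["dsigma_at_lower_bound"],
        )

    def model_log_fc(theta: np.ndarray) -> np.ndarray:
        s_rich, s_min, ds = theta
        sigma0 = np.where(is_rich, s_rich, s_min)
        g0 = base + _g_twist_grid(sigma0, mp)
        g1 = base + _g_twist_grid(sigma0 + ds, mp)
        return log_relative_rate(g1, mp, tp) - log_relative_rate(g0, mp, tp)

    def objective(theta: np.ndarray) -> float:
        return float(np.sum((model_log_fc(theta) - log_fc_obs) ** 2))

    bounds = [sigma_bounds, sigma_bounds, dsigma_bounds]
    best = None
    for s_r in _SHOCK_START_SIGMAS:
        for s_m in _SHOCK_START_SIGMAS:
            for ds in _SHOCK_START_DSIGMAS:
                res = optimize.minimize(
                    objective,
                    x0=np.array([s_r, s_m, ds]),
                    method="Nelder-Mead",
                    bounds=bounds,
                    options={
                        "xatol": 1e-9,
                        "fatol": 1e-14,
                        "maxiter": 2000,
                    },
                )
                if best is None or res.fun < best.fun:
                    best = res
    # polish the winner from its own solution
    res = optimize.minimize(
        objective,
        x0=best.x,
        method="Nelder-Mead",
        bounds=bounds,
        options={"xatol": 1e-11, "fatol": 1e-16, "maxiter": 4000},
    )
    if res.fun <= best.fun:
        best = res
    flags: list[str] = []
    if best.x[2] <= 2.0 * dsigma_bounds[0]:
        flags.append("dsigma_at_lower_bound")
        logger.warning("shock fit: dsigma stuck at lower bound (no signal)")
    return ShockFit(
        sigma_rich=float(best.x[0]),
        sigma_min=float(best.x[1]),
        dsigma=float(best.x[2]),
        residual=float(best.fun),
        n_obs=len(obs),
        flags=flags,
    )
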