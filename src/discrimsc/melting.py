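"""Supercoiling-dependent cost of opening the 14-bp transcription bubble.

The model is an imposed-bubble two-state description of promoter opening:
a fixed 14-bp window starting at the -10 hexamer is denatured, at a free
energy cost composed of

* the duplex stability lost over the 15 stacks spanning the bubble
  (nearest-neighbor table at 1 M salt with a per-stack log-salt
  correction; flanking neighbors outside the promoter window are taken
  as G, emulating G-tract flanks),
* a sequence-independent bubble nucleation penalty ``a_nuc``, and
* a torsional term from the redistribution of superhelical stress: the
  denatured strands can absorb part of the linking difference by
  unwinding, trading single-strand torsion against the quadratic
  superhelical energy ``E_sc(dLk) = B * R * T * dLk^2 / N`` of the
  remaining duplex in a topological domain of N bp.

The torsional term is minimized in closed form over the single-strand
twist, so the opening cost is a smooth, exactly quadratic function of
the superhelical density sigma.  Negative sigma lowers the cost; the
effective salt concentration is a calibration parameter absorbing the
simplified solvent description.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .seq_io import CoordinateError, PromoterRecord

__all__ = [
    "NN_DG37_1M",
    "R_KCAL",
    "MeltingParams",
    "TwistSolution",
    "OpeningProfile",
    "stack_opening_cost",
    "bubble_melting_cost",
    "bubble_melting_costs",
    "twist_relaxation_cost",
    "twist_energy",
    "opening_cost",
    "opening_profile",
]

#: Gas constant in kcal/(mol*K).
R_KCAL = 1.987204259e-3

#: Unified nearest-neighbor duplex stabilities dG(37 C, 1 M NaCl) in
#: kcal/mol per stack (SantaLucia 1998 unified parameter set), keyed by
#: the 5'->3' dinucleotide on the coding strand.
NN_DG37_1M: Mapping[str, float] = {
    "AA": -1.00, "AT": -0.88, "AC": -1.44, "AG": -1.28,
    "TA": -0.58, "TT": -1.00, "TC": -1.30, "TG": -1.45,
    "CA": -1.45, "CT": -1.28, "CC": -1.84, "CG": -2.17,
    "GA": -1.30, "GT": -1.44, "GC": -2.24, "GG": -1.84,
}


@dataclass
class MeltingParams:
    """Physical constants of the opening-energy model.

    h
        Helical repeat of B-DNA, bp/turn.
    N
        Topological domain size, bp (plasmid-like default).
    B
        Dimensionless coefficient of the quadratic superhelical energy
        ``E_sc(dLk) = B * R * T * dLk**2 / N``.
    C_ss
        Torsional stiffness of denatured single strands,
        kcal/(mol * bp * rad**2).
    a_nuc
        Bubble nucleation penalty, kcal/mol.  For a fixed 14-bp bubble it
        is sequence independent and therefore degenerate with the RNAP
        assistance energy of the rate law; it is kept separate for
        physical bookkeeping only.
    salt
        Effective monovalent salt concentration, mol/L.  A calibration
        parameter, not a physiological concentration: the default
        (0.5 mM) places the opening transition of an average promoter
        near sigma = -0.045 and keeps the genome-wide response regime
        stable under global sigma shifts of +-0.01.
    T
        Temperature, K.
    n_bubble
        Bubble length in bp (14 for the open complex).
    m_salt
        Per-stack salt coefficient, kcal/mol per ln-unit of [salt].
    nn_table
        16-entry nearest-neighbor duplex stability table at 1 M salt.
    """

    h: float = 10.5
    N: float = 3000.0
    B: float = 1100.0
    C_ss: float = 1.0
    a_nuc: float = 10.0
    salt: float = 5e-4
    T: float = 310.15
    n_bubble: int = 14
    m_salt: float = 0.114
    nn_table: Mapping[str, float] = field(default_factory=lambda: dict(NN_DG37_1M))

    def __post_init__(self) -> None:
        if self.h <= 0 or self.C_ss <= 0 or self.salt <= 0 or self.T <= 0:
            raise ValueError("h, C_ss, salt and T must be positive")
        if self.N <= self.n_bubble:
            raise ValueError("domain size N must exceed the bubble length")
        if self.n_bubble < 0:
            raise ValueError("n_bubble must be non-negative")
        missing = [s for s in NN_DG37_1M if s not in self.nn_table]
        if missing:
            raise ValueError(f"nn_table incomplete, missing steps {missing}")

    @property
    def kBT(self) -> float:
        """Thermal energy R*T in kcal/mol."""
        return R_KCAL * self.T

    def with_salt(self, salt: float) -> "MeltingParams":
        return replace(self, salt=salt)


@dataclass
class TwistSolution:
    """Optimal torsional state of the denatured bubble at one sigma."""

    alpha: float  #: linking difference of the domain, turns
    tau_star: float  #: optimal single-strand twist, rad/bp
    alpha_res: float  #: residual linking difference carried by the duplex
    g_twist: float  #: torsional/superhelical opening contribution, kcal/mol


@dataclass
class OpeningProfile:
    """Opening cost of one promoter along a grid of superhelical densities."""

    promoter_id: str
    sigma_grid: np.ndarray
    g_cost: np.ndarray


def stack_opening_cost(step: str, params: MeltingParams) -> float:
    """Free-energy cost of disrupting one dinucleotide stack, kcal/mol.

    ``-dG_NN(step, 1 M) + m_salt * ln(salt)``: below 1 M the logarithmic
    correction is negative, i.e. opening is cheaper at low salt.
    """
    step = step.upper()
    if step not in params.nn_table:
        raise ValueError(f"unknown dinucleotide step {step!r}")
    return -params.nn_table[step] + params.m_salt * float(np.log(params.salt))


def _bubble_with_flanks(promoter: PromoterRecord, params: MeltingParams) -> str:
    """Bubble sequence plus one flanking base on each side (G if absent)."""
    m10 = promoter.minus10_offset
    if m10 is None:
        raise CoordinateError(f"promoter {promoter.id}: minus10_offset missing")
    lo, hi = m10, m10 + params.n_bubble - 1
    if not promoter.covers(lo, hi):
        raise CoordinateError(
            f"promoter {promoter.id}: bubble [{lo}, {hi}] not covered by window"
        )
    left = promoter.base_at(lo - 1) if promoter.covers(lo - 1, lo - 1) else "G"
    right = promoter.base_at(hi + 1) if promoter.covers(hi + 1, hi + 1) else "G"
    return left + promoter.subseq(lo, hi) + right


def bubble_melting_cost(promoter: PromoterRecord, params: MeltingParams) -> float:
    """Duplex-stability cost of denaturing the bubble, kcal/mol.

    Sums the ``n_bubble + 1`` stacks spanning the 14-bp window that starts
    at (and includes) the -10 hexamer, including the two boundary stacks;
    a boundary neighbor outside the promoter window is taken to be G.
    """
    if params.n_bubble == 0:
        return 0.0
    seq = _bubble_with_flanks(promoter, params)
    return sum(
        stack_opening_cost(seq[i : i + 2], params) for i in range(len(seq) - 1)
    )


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _nn_matrix(params: MeltingParams) -> np.ndarray:
    bases = "ACGT"
    m = np.empty((4, 4))
    for i, a in enumerate(bases):
        for j, b in enumerate(bases):
            m[i, j] = params.nn_table[a + b]
    return m


def bubble_melting_costs(
    promoters: Sequence[PromoterRecord], params: MeltingParams
) -> np.ndarray:
    """Vectorized :func:`bubble_melting_cost` over a promoter set."""
    if params.n_bubble == 0:
        return np.zeros(len(promoters))
    nn = _nn_matrix(params)
    salt_term = params.m_salt * np.log(params.salt)
    n_stacks = params.n_bubble + 1
    seqs = np.array(
        [
            [_BASE_INDEX[b] for b in _bubble_with_flanks(p, params)]
            for p in promoters
        ],
        dtype=np.intp,
    )
    dg = nn[seqs[:, :-1], seqs[:, 1:]].sum(axis=1)
    return -dg + n_stacks * salt_term


def twist_energy(tau, sigma: float, params: MeltingParams):
    """Energy of the open state at single-strand twist ``tau`` (rad/bp).

    ``f(tau) = C_ss*n/2 * tau**2 + B*R*T/N * (alpha + n/h - n*tau/(2*pi))**2``
    where ``alpha = sigma * N / h`` is the linking difference of the
    domain.  Exposed for oracle-style grid minimization.
    """
    n = params.n_bubble
    K = params.B * R_KCAL * params.T / params.N
    alpha = sigma * params.N / params.h
    x = alpha + n / params.h - n * np.asarray(tau) / (2.0 * np.pi)
    return 0.5 * params.C_ss * n * np.asarray(tau) ** 2 + K * x**2


def twist_relaxation_cost(sigma: float, params: MeltingParams) -> TwistSolution:
    """Minimized torsional/superhelical contribution to the opening cost.

    The objective is quadratic in the single-strand twist, so the
    minimizer is the closed form
    ``tau* = (K/pi) * (alpha + n/h) / (C_ss + K*n/(2*pi**2))``
    with ``K = B*R*T/N``; the returned ``g_twist`` is the minimized open
    state energy minus the closed-state superhelical energy
    ``K * alpha**2``.
    """
    n = params.n_bubble
    K = params.B * R_KCAL * params.T / params.N
    alpha = sigma * params.N / params.h
    if n == 0:
        return TwistSolution(alpha=alpha, tau_star=0.0, alpha_res=alpha, g_twist=0.0)
    x0 = alpha + n / params.h
    tau_star = (K / np.pi) * x0 / (params.C_ss + K * n / (2.0 * np.pi**2))
    alpha_res = x0 - n * tau_star / (2.0 * np.pi)
    g = float(twist_energy(tau_star, sigma, params) - K * alpha**2)
    return TwistSolution(
        alpha=alpha, tau_star=float(tau_star), alpha_res=float(alpha_res), g_twist=g
    )


def _g_twist_grid(sigma: np.ndarray, params: MeltingParams) -> np.ndarray:
    """Vectorized ``g_twist`` over an array of superhelical densities."""
    n = params.n_bubble
    if n == 0:
        return np.zeros_like(np.asarray(sigma, dtype=float))
    K = params.B * R_KCAL * params.T / params.N
    alpha = np.asarray(sigma, dtype=float) * params.N / params.h
    x0 = alpha + n / params.h
    tau_star = (K / np.pi) * x0 / (params.C_ss + K * n / (2.0 * np.pi**2))
    x = x0 - n * tau_star / (2.0 * np.pi)
    f = 0.5 * params.C_ss * n * tau_star**2 + K * x**2
    return f - K * alpha**2


def opening_cost(
    promoter: PromoterRecord, sigma: float, params: MeltingParams
) -> float:
    """Total free-energy cost of opening the bubble at ``sigma``, kcal/mol.

    ``a_nuc + bubble_melting_cost + g_twist(sigma)``.  This is the
    positive opening cost; strongly negative supercoiling makes it
    negative (opening releases superhelical stress).
    """
    return (
        params.a_nuc
        + bubble_melting_cost(promoter, params)
        + twist_relaxation_cost(sigma, params).g_twist
    )


def opening_profile(
    promoter: PromoterRecord,
    sigma_grid: Sequence[float],
    params: MeltingParams,
) -> OpeningProfile:
    """Opening cost along a sorted grid of superhelical densities."""
    grid = np.asarray(sigma_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("sigma_grid must be non-empty")
    if np.any(np.diff(grid) < 0):
        raise ValueError("sigma_grid must be sorted ascending")
    base = params.a_nuc + bubble_melting_cost(promoter, params)
    return OpeningProfile(
        promoter_id=promoter.id,
        sigma_grid=grid,
        g_cost=base + _g_twist_grid(grid, params),
    )
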