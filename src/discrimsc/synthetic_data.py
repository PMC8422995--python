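"""Synthetic promoter sets and supercoiling-response transcriptomes.

The generator replaces downloaded transcriptomes and promoter catalogs
with data of known ground truth: promoters carry a near-consensus -10
hexamer, a discriminator window of controlled A/T composition and
random flanking sequence; their transcriptome response to a supercoiling
shift is produced by inverting the package's own rate model (with sum
normalization), then corrupted by multiplicative noise and by a fraction
of confounded promoters whose response is replaced by an unrelated
random draw (emulating TF-driven or otherwise discriminator-independent
responders).  Adjusted p-values are generated analytically from a
pseudo-replicate z-model rather than by simulating replicates.

Everything is a pure function of the configuration, including its seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome_predictor import predict_genomewide
from .melting import MeltingParams
from .seq_io import ExpressionRecord, PromoterRecord
from .transcription import TranscriptionParams, activation_curve

__all__ = [
    "SynthConfig",
    "ResponseSimulation",
    "MINUS10_CONSENSUS",
    "generate_promoters",
    "generate_response",
    "generate_activation_curves",
]

MINUS10_CONSENSUS = "TATAAT"

#: Discriminator window used by the generator, internal offsets (TSS = 0).
_DISC_OFFSETS = (-4, -3, -2, -1, 0)


@dataclass
class SynthConfig:
    """Study conditions of the synthetic transcriptome.

    The defaults emulate a genome-wide DNA relaxation assay: 2000
    sigma70 promoters, initial level sigma0 = -0.045 relaxed by
    dsigma = +0.015, log2 fold changes observed with additive noise of
    0.3 and 30% of promoters responding through discriminator-independent
    pathways.  ``replicates_m`` mirrors triplicate assays in the
    analytic p-value model; ``anticorrelation_strength`` couples -10
    consensus match with discriminator G/C content (0 = no coupling).
    """

    n_promoters: int = 2000
    seed: int = 1
    window_span: tuple[int, int] = (50, 20)
    minus10_offset: int = -12
    discriminator_at_weights: Sequence[float] = field(
        default_factory=lambda: [1 / 6] * 6
    )
    minus10_mutation_rate: float = 0.15
    background_gc: float = 0.5
    sigma0: float = -0.045
    dsigma: float = 0.015
    noise_sd: float = 0.3
    confounder_frac: float = 0.3
    replicates_m: int = 3
    anticorrelation_strength: float = 0.0

    def __post_init__(self) -> None:
        w = np.asarray(self.discriminator_at_weights, dtype=float)
        if w.shape != (6,) or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError(
                "discriminator_at_weights must be 6 non-negative weights summing to 1"
            )
        for name in ("confounder_frac", "minus10_mutation_rate", "background_gc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class ResponseSimulation:
    """Simulated transcriptome plus its ground truth."""

    records: list[ExpressionRecord]
    truth: pd.DataFrame  #: columns id, true_log2fc, observed_log2fc, confounder


def generate_promoters(cfg: SynthConfig) -> list[PromoterRecord]:
    """Generate a seeded promoter set.

    Background bases are drawn at the configured G/C content, the -10
    hexamer starts from the TATAAT consensus with a per-base mutation
    probability, and the 5-nt discriminator window (internal offsets
    -4..0) gets an A/T count drawn from ``discriminator_at_weights``.
    With ``anticorrelation_strength > 0``, A/T-rich discriminators get
    proportionally more -10 mutations, planting a negative correlation
    between -10 consensus match and discriminator A/T content.
    """
    rng = np.random.default_rng(cfg.seed)
    up, down = cfg.window_span
    length = up + down + 1
    gc = cfg.background_gc
    base_probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    bases = np.array(list("ACGT"))
    at_bases = np.array(list("AT"))
    gcb = np.array(list("GC"))
    at_counts_all = rng.choice(
        6, size=cfg.n_promoters, p=np.asarray(cfg.discriminator_at_weights)
    )
    promoters: list[PromoterRecord] = []
    for i in range(cfg.n_promoters):
        seq = rng.choice(bases, size=length, p=base_probs)
        # -10 hexamer: consensus with per-base deviations
        at_count = int(at_counts_all[i])
        rate = cfg.minus10_mutation_rate * (
            1.0 + cfg.anticorrelation_strength * (2.0 * at_count / 5.0 - 1.0)
        )
        rate = float(np.clip(rate, 0.0, 1.0))
        m10 = cfg.minus10_offset
        for j, cons in enumerate(MINUS10_CONSENSUS):
            if rng.random() < rate:
                others = [b for b in "ACGT" if b != cons]
                seq[m10 + j + up] = others[rng.integers(3)]
            else:
                seq[m10 + j + up] = cons
        # discriminator window with the drawn A/T count
        which_at = rng.permutation(5) < at_count
        for off, is_at in zip(_DISC_OFFSETS, which_at):
            pool = at_bases if is_at else gcb
            seq[off + up] = pool[rng.integers(2)]
        pid = f"P{i:05d}"
        promoters.append(
            PromoterRecord(
                id=pid,
                seq="".join(seq),
                up=up,
                tss_genome_pos=1000 * (i + 1),
                strand="+",
                minus10_offset=cfg.minus10_offset,
                sigma="sigma70",
                genes=[f"{pid}_g1"],
            )
        )
    return promoters


def generate_response(
    promoters: Sequence[PromoterRecord],
    cfg: SynthConfig,
    mp: MeltingParams | None = None,
    tp: TranscriptionParams | None = None,
) -> ResponseSimulation:
    """Simulate a differential-expression table for a sigma shift.

    True log2 fold changes come from the sum-normalized genome-wide
    prediction at ``(sigma0, dsigma)``; a ``confounder_frac`` fraction of
    promoters has its true value replaced by Normal(0, 2*noise_sd);
    observed = true + Normal(0, noise_sd).  Two-sided p-values follow the
    z-statistic ``observed * sqrt(m) / noise_sd`` of an m-replicate
    design and are Benjamini-Hochberg adjusted across promoters.
    """
    if cfg.noise_sd <= 0:
        raise ValueError("noise_sd must be positive to generate p-values")
    mp = mp or MeltingParams()
    tp = tp or TranscriptionParams()
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 7)))
    pred = predict_genomewide(promoters, cfg.sigma0, cfg.dsigma, mp, tp)
    true_l2fc = np.log2(pred["fc_norm"].to_numpy())
    n = len(promoters)
    confounder = rng.random(n) < cfg.confounder_frac
    true_l2fc = np.where(
        confounder, rng.normal(0.0, 2.0 * cfg.noise_sd, size=n), true_l2fc
    )
    observed = true_l2fc + rng.normal(0.0, cfg.noise_sd, size=n)
    z = observed * np.sqrt(cfg.replicates_m) / cfg.noise_sd
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    padj = multipletests(pvals, method="fdr_bh")[1]
    records = [
        ExpressionRecord(id=p.id, log2fc=float(observed[i]), padj=float(padj[i]))
        for i, p in enumerate(promoters)
    ]
    truth = pd.DataFrame(
        {
            "id": [p.id for p in promoters],
            "true_log2fc": true_l2fc,
            "observed_log2fc": observed,
            "confounder": confounder,
        }
    )
    return ResponseSimulation(records=records, truth=truth)


def generate_activation_curves(
    promoters: Sequence[PromoterRecord],
    sigma_grid: Sequence[float],
    salt_true: float,
    dgp0_true: float,
    noise_rel: float = 0.0,
    seed: int = 0,
    mp: MeltingParams | None = None,
) -> pd.DataFrame:
    """Simulate expression-versus-sigma calibration curves.

    Model ``k/k0`` at the stated true salt and RNAP assistance, times
    log-normal noise of relative magnitude ``noise_rel``.  Returns a tidy
    frame (promoter_id, sigma, expression) shaped like microplate
    relative-expression curves.
    """
    grid = np.asarray(sigma_grid, dtype=float)
    if np.any(np.diff(grid) < 0):
        raise ValueError("sigma_grid must be sorted ascending")
    mp = (mp or MeltingParams()).with_salt(salt_true)
    tp = TranscriptionParams(dgp0=dgp0_true)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 13)))
    rows = []
    for p in promoters:
        rate = activation_curve(p, grid, mp, tp).rate
        if noise_rel > 0:
            rate = rate * rng.lognormal(0.0, noise_rel, size=rate.shape)
        for s, r in zip(grid, rate):
            rows.append({"promoter_id": p.id, "sigma": s, "expression": r})
    return pd.DataFrame(rows)
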