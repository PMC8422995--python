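"""Genome-wide discriminator sequence statistics.

Promoters are placed on a common position axis (aligned at the -10
element where available, otherwise at the TSS, optionally with a global
shift for species with offset signals).  A/T% is computed in sliding
5-nt windows and compared between promoters activated and repressed by
a supercoiling change: per-position Welch tests, classification of
discriminator A/T% into the six 5-nt levels (0, 20, ..., 100) with
activated proportions, Wilson confidence intervals, a linear regression
of the binary outcome on A/T%, and a chi-square independence test.
The "non" group is profiled for display but never enters tests.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .seq_io import (
    CoordinateError,
    PromoterRecord,
    display_to_internal,
    internal_to_display,
)

__all__ = [
    "AlignedPromoterSet",
    "ProfileResult",
    "BinClassification",
    "align_promoters",
    "at_profile",
    "discriminator_at",
    "discriminator_variable",
    "position_ttest",
    "classify_and_regress",
    "minus10_pwm_correlation",
    "significance_stars",
]

#: Aligned position of the first -10 hexamer base under minus10 anchoring.
MINUS10_ANCHOR_POS = -12

AT_BINS = (0, 20, 40, 60, 80, 100)


def significance_stars(p: float) -> str:
    """Significance label: *** p<0.001, ** p<0.01, * p<0.05, ns above."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class AlignedPromoterSet:
    """Promoters on a common internal position axis.

    With ``anchor="minus10"`` every promoter's -10 hexamer starts at
    aligned position -12; with ``anchor="tss"`` the TSS base sits at
    aligned position 0.  ``shift`` adds a constant to all aligned
    positions (e.g. -4 to move an off-register species signal onto the
    -10 register).  Aligned positions are contiguous internal offsets;
    display labels skip 0.
    """

    promoters: list[PromoterRecord]
    anchor: str = "minus10"
    shift: int = 0

    def _delta(self, rec: PromoterRecord) -> int:
        """aligned = internal + delta."""
        if self.anchor == "minus10":
            if rec.minus10_offset is None:
                raise ValueError(f"promoter {rec.id}: minus10_offset missing")
            return MINUS10_ANCHOR_POS - rec.minus10_offset + self.shift
        return self.shift

    def covered_range(self) -> tuple[int, int]:
        """Aligned positions covered by every promoter of the set."""
        los, his = [], []
        for rec in self.promoters:
            d = self._delta(rec)
            los.append(rec.min_offset + d)
            his.append(rec.max_offset + d)
        return max(los), min(his)

    def window_at(self, rec: PromoterRecord, center: int, width: int) -> str:
        """Bases of ``rec`` in a window centered at an aligned position."""
        d = self._delta(rec)
        half = width // 2
        return rec.subseq(center - half - d, center + half - d)


def align_promoters(
    promoters: Sequence[PromoterRecord],
    anchor: str = "minus10",
    shift: int = 0,
) -> AlignedPromoterSet:
    """Build an aligned set, validating the required anchor annotation."""
    if anchor not in ("minus10", "tss"):
        raise ValueError("anchor must be 'minus10' or 'tss'")
    if anchor == "minus10":
        missing = [p.id for p in promoters if p.minus10_offset is None]
        if missing:
            raise ValueError(
                f"anchor='minus10' but {len(missing)} promoters lack a -10 "
                f"offset (e.g. {missing[:3]})"
            )
    return AlignedPromoterSet(list(promoters), anchor=anchor, shift=shift)


def _window_at_pct(seq: str) -> float:
    return 100.0 * sum(b in "AT" for b in seq) / len(seq)


@dataclass
class ProfileResult:
    """Per-position A/T% statistics by response group.

    ``table`` columns: position (display convention), group, mean, se, n.
    The 67% band of the profile figures is mean +- 1 SE; 95% bands use
    the Student multiplier.
    """

    table: pd.DataFrame
    window: int

    def band(self, group: str, level: float = 0.67) -> pd.DataFrame:
        sub = self.table[self.table["group"] == group].copy()
        if level == 0.67:
            mult = np.ones(len(sub))
        else:
            mult = stats.t.ppf(0.5 + level / 2.0, sub["n"] - 1)
        sub["lo"] = sub["mean"] - mult * sub["se"]
        sub["hi"] = sub["mean"] + mult * sub["se"]
        return sub


def at_profile(
    aligned: AlignedPromoterSet,
    calls: pd.DataFrame,
    window: int = 5,
) -> ProfileResult:
    """Sliding-window A/T% profile per response group.

    Only aligned center positions whose full window is covered by every
    promoter are profiled, so group sizes are constant along the axis.
    """
    if window % 2 != 1:
        raise ValueError("window must be odd")
    call_of = dict(zip(calls["id"], calls["call"]))
    groups: dict[str, list[PromoterRecord]] = {"act": [], "rep": [], "non": []}
    for rec in aligned.promoters:
        c = call_of.get(rec.id)
        if c in groups:
            groups[c].append(rec)
    lo, hi = aligned.covered_range()
    half = window // 2
    centers = np.arange(lo + half, hi - half + 1)
    rows = []
    for gname, members in groups.items():
        if not members:
            continue
        mat = np.array(
            [
                [_window_at_pct(aligned.window_at(r, int(c), window)) for c in centers]
                for r in members
            ]
        )
        mean = mat.mean(axis=0)
        n = len(members)
        se = mat.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(len(centers))
        for c, m, s in zip(centers, mean, se):
            rows.append(
                {
                    "position": internal_to_display(int(c)),
                    "group": gname,
                    "mean": m,
                    "se": s,
                    "n": n,
                }
            )
    return ProfileResult(
        table=pd.DataFrame(rows, columns=["position", "group", "mean", "se", "n"]),
        window=window,
    )


def discriminator_at(
    promoter: PromoterRecord,
    center: int = -2,
    width: int = 5,
) -> float:
    """A/T% of the discriminator classification window.

    ``center`` is a display position (default -2, i.e. the 5-nt window
    spanning internal offsets -4..0); species with downstream-shifted
    signals use e.g. center=+4.  Returns a multiple of 100/width.
    """
    c = display_to_internal(center)
    half = width // 2
    return _window_at_pct(promoter.subseq(c - half, c + half))


def discriminator_variable(promoter: PromoterRecord) -> float:
    """A/T% of the variable-length discriminator (between -10 and +1).

    Alternative extractor covering internal offsets
    ``minus10_offset + 6 .. -1``; requires the -10 annotation.
    """
    if promoter.minus10_offset is None:
        raise CoordinateError(f"promoter {promoter.id}: minus10_offset missing")
    start = promoter.minus10_offset + 6
    if start > -1:
        raise CoordinateError(f"promoter {promoter.id}: empty discriminator")
    return _window_at_pct(promoter.subseq(start, -1))


def _group_at_values(
    aligned: AlignedPromoterSet,
    calls: pd.DataFrame,
    position: int,
    window: int,
) -> dict[str, np.ndarray]:
    call_of = dict(zip(calls["id"], calls["call"]))
    center = display_to_internal(position)
    out: dict[str, list[float]] = {"act": [], "rep": [], "non": []}
    for rec in aligned.promoters:
        c = call_of.get(rec.id)
        if c in out:
            out[c].append(_window_at_pct(aligned.window_at(rec, center, window)))
    return {k: np.asarray(v) for k, v in out.items()}


def position_ttest(
    aligned: AlignedPromoterSet,
    calls: pd.DataFrame,
    position: int,
    window: int = 5,
) -> tuple[float, float]:
    """Welch two-sample t-test of A/T% between act and rep at a position.

    ``position`` uses the display convention.  Returns (t, two-sided p);
    identical groups give t=0, p=1.
    """
    vals = _group_at_values(aligned, calls, position, window)
    act, rep = vals["act"], vals["rep"]
    if len(act) < 2 or len(rep) < 2:
        raise ValueError("both act and rep groups need at least 2 promoters")
    if np.ptp(act) == 0 and np.ptp(rep) == 0 and act.mean() == rep.mean():
        return 0.0, 1.0
    t, p = stats.ttest_ind(act, rep, equal_var=False)
    return float(t), float(p)


@dataclass
class BinClassification:
    """Activated proportions across discriminator A/T% levels.

    ``bins`` columns: at_pct, n_act, n_rep, proportion_act, ci_lo, ci_hi
    (Wilson 95%).  The regression is ordinary least squares of the binary
    outcome (act=1, rep=0) on per-promoter A/T% by default, or on binned
    proportions in ``regression='binned'`` mode; the chi-square test
    compares the act/rep-by-bin contingency table after merging bins with
    expected counts below 5 into neighbors.
    """

    bins: pd.DataFrame
    slope: float
    slope_p: float
    intercept: float
    chi2: float
    chi2_p: float
    n_responsive: int

    @property
    def stars(self) -> str:
        return significance_stars(self.slope_p)


def _merge_small_bins(table: np.ndarray) -> np.ndarray:
    """Merge adjacent contingency columns until all expected counts >= 5."""
    tab = table.astype(float)
    while tab.shape[1] > 2:
        total = tab.sum()
        expected = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / total
        if expected.min() >= 5:
            break
        j = int(np.argmin(tab.sum(axis=0)))
        if j == 0:
            k = 1
        elif j == tab.shape[1] - 1:
            k = j - 1
        else:  # neighbor with the smaller column total, ties to the left
            k = j - 1 if tab[:, j - 1].sum() <= tab[:, j + 1].sum() else j + 1
        tab[:, min(j, k)] += tab[:, max(j, k)]
        tab = np.delete(tab, max(j, k), axis=1)
    return tab


def classify_and_regress(
    aligned: AlignedPromoterSet,
    calls: pd.DataFrame,
    center: int = -2,
    width: int = 5,
    regression: str = "binary",
) -> BinClassification:
    """Activated-proportion analysis across discriminator A/T% bins."""
    call_of = dict(zip(calls["id"], calls["call"]))
    c_int = display_to_internal(center)
    at_vals, outcomes = [], []
    for rec in aligned.promoters:
        c = call_of.get(rec.id)
        if c in ("act", "rep"):
            at_vals.append(_window_at_pct(aligned.window_at(rec, c_int, width)))
            outcomes.append(1.0 if c == "act" else 0.0)
    at_arr = np.asarray(at_vals)
    y = np.asarray(outcomes)
    n_resp = len(y)
    if n_resp < 10:
        raise ValueError("need at least 10 responsive promoters")

    levels = [round(100.0 * k / width) for k in range(width + 1)]
    rows = []
    for lv in levels:
        mask = np.isclose(at_arr, lv)
        n_act = int(y[mask].sum())
        n_rep = int(mask.sum() - n_act)
        if n_act + n_rep:
            prop = n_act / (n_act + n_rep)
            lo, hi = proportion_confint(n_act, n_act + n_rep, method="wilson")
        else:
            prop, lo, hi = np.nan, np.nan, np.nan
        rows.append(
            {
                "at_pct": lv,
                "n_act": n_act,
                "n_rep": n_rep,
                "proportion_act": prop,
                "ci_lo": lo,
                "ci_hi": hi,
            }
        )
    bins = pd.DataFrame(rows)

    if np.ptp(at_arr) == 0:
        raise ValueError("all responsive promoters in one A/T bin: regression "
                         "is not identifiable")
    if regression == "binary":
        X = sm.add_constant(at_arr)
        fit = sm.OLS(y, X).fit()
        slope, slope_p = float(fit.params[1]), float(fit.pvalues[1])
        intercept = float(fit.params[0])
    elif regression == "binned":
        ok = bins["proportion_act"].notna()
        X = sm.add_constant(bins.loc[ok, "at_pct"].to_numpy(dtype=float))
        fit = sm.OLS(bins.loc[ok, "proportion_act"].to_numpy(), X).fit()
        slope, slope_p = float(fit.params[1]), float(fit.pvalues[1])
        intercept = float(fit.params[0])
    else:
        raise ValueError("regression must be 'binary' or 'binned'")
    if np.ptp(y) == 0:
        slope_p = np.nan  # degenerate outcome: every responsive promoter agrees

    occupied = bins[(bins["n_act"] + bins["n_rep"]) > 0]
    table = np.vstack([occupied["n_act"].to_numpy(), occupied["n_rep"].to_numpy()])
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] >= 2 and np.all(table.sum(axis=1) > 0):
        merged = _merge_small_bins(table)
        chi2, chi2_p, _, _ = stats.chi2_contingency(merged, correction=False)
    else:
        chi2, chi2_p = np.nan, np.nan
    return BinClassification(
        bins=bins,
        slope=slope,
        slope_p=slope_p,
        intercept=intercept,
        chi2=float(chi2),
        chi2_p=float(chi2_p),
        n_responsive=n_resp,
    )


def minus10_pwm_correlation(
    aligned: AlignedPromoterSet,
    center: int = -2,
    width: int = 5,
    pseudocount: float = 1.0,
) -> tuple[float, float]:
    """Correlation between -10 binding score and discriminator A/T%.

    Builds a log-odds position weight matrix from the aligned -10
    hexamers of the input set (pseudocount added, background = base
    frequencies over the full promoter windows), scores each promoter's
    -10 element, and returns the Pearson correlation (r, p) of score
    versus discriminator A/T%.
    """
    if aligned.anchor != "minus10":
        raise ValueError("minus10_pwm_correlation requires anchor='minus10'")
    proms = aligned.promoters
    if len(proms) < 10:
        raise ValueError("need at least 10 promoters")
    hexamers = [
        p.subseq(
            MINUS10_ANCHOR_POS - aligned._delta(p),
            MINUS10_ANCHOR_POS - aligned._delta(p) + 5,
        )
        for p in proms
    ]
    base_order = "ACGT"
    counts = np.full((4, 6), pseudocount, dtype=float)
    for hx in hexamers:
        for j, b in enumerate(hx):
            counts[base_order.index(b), j] += 1.0
    freqs = counts / counts.sum(axis=0, keepdims=True)
    bg_counts = np.zeros(4)
    for p in proms:
        for b in p.seq:
            bg_counts[base_order.index(b)] += 1.0
    bg = bg_counts / bg_counts.sum()
    logodds = np.log2(freqs / bg[:, None])
    scores = np.array(
        [
            sum(logodds[base_order.index(b), j] for j, b in enumerate(hx))
            for hx in hexamers
        ]
    )
    at_vals = np.array([discriminator_at(p, center, width) for p in proms])
    if np.ptp(scores) == 0 or np.ptp(at_vals) == 0:
        raise ValueError("zero variance in -10 scores or discriminator A/T%")
    r, p = stats.pearsonr(scores, at_vals)
    return float(r), float(p)
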