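"""Cell-conjugation binding quantification and curve fitting.

Covers the flow-cytometry side of the pipeline: quadrant gating of
two-colour event tables, percent-bound and relative-binding normalisation,
threshold classification of mutant binding losses, salt-bridge suppressor
rescue detection, Hill-equation titration fits, and competition profiles.

Percent bound is the fraction of events positive in both fluorescence
channels (cell-cell conjugates); a mutant's relative binding is its percent
bound as a percentage of the wild-type interaction's percent bound.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .synthetic import hill_response

__all__ = [
    "GateSpec",
    "GatedCounts",
    "HillFit",
    "LossCall",
    "RescuePair",
    "CompetitionFit",
    "gate_events",
    "percent_bound",
    "relative_binding",
    "classify_losses",
    "fit_hill",
    "competition_profile",
    "suppressor_rescue",
]

LOSS_THRESHOLDS = (25.0, 50.0, 70.0)


# ---------------------------------------------------------------------------
# Gating
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GateSpec:
    """Quadrant gate: an event is positive in a channel iff its intensity is
    strictly greater than that channel's threshold."""

    green_threshold: float
    red_threshold: float

    def __post_init__(self) -> None:
        if self.green_threshold <= 0 or self.red_threshold <= 0:
            raise ValueError("gate thresholds must be > 0")

    @classmethod
    def from_negative_control(cls, control: pd.DataFrame,
                              percentile: float = 99.5) -> "GateSpec":
        """Derive thresholds as a percentile of an unstained / negative
        control event table (default 99.5th per channel)."""
        return cls(
            green_threshold=float(np.percentile(control["green"], percentile)),
            red_threshold=float(np.percentile(control["red"], percentile)),
        )


@dataclass(frozen=True)
class GatedCounts:
    """Quadrant counts; the four categories always partition ``n_total``."""

    n_total: int
    n_double_positive: int
    n_green_only: int
    n_red_only: int
    n_double_negative: int

    def __post_init__(self) -> None:
        parts = (self.n_double_positive + self.n_green_only
                 + self.n_red_only + self.n_double_negative)
        if parts != self.n_total:
            raise ValueError("quadrant counts must sum to n_total")


def gate_events(events: pd.DataFrame, gate: GateSpec) -> GatedCounts:
    """Assign each event to exactly one quadrant by strict comparison.

    ``events`` needs columns ``green`` and ``red`` (arbitrary fluorescence
    units, finite and >= 0).  An event exactly at a threshold is negative.
    """
    if len(events) == 0:
        raise ValueError("cannot gate an empty event table")
    green = np.asarray(events["green"], dtype=float)
    red = np.asarray(events["red"], dtype=float)
    bad = ~(np.isfinite(green) & np.isfinite(red))
    if bad.any():
        raise ValueError(
            f"non-finite intensity at row {int(np.flatnonzero(bad)[0])}")
    gpos = green > gate.green_threshold
    rpos = red > gate.red_threshold
    return GatedCounts(
        n_total=len(events),
        n_double_positive=int((gpos & rpos).sum()),
        n_green_only=int((gpos & ~rpos).sum()),
        n_red_only=int((~gpos & rpos).sum()),
        n_double_negative=int((~gpos & ~rpos).sum()),
    )


def percent_bound(counts: GatedCounts) -> float:
    """Percentage bound: double-positive events over total events, x100."""
    if counts.n_total <= 0:
        raise ValueError("n_total must be > 0")
    return 100.0 * counts.n_double_positive / counts.n_total


def relative_binding(p_mut: float, p_wt: float) -> float:
    """Mutant percent bound as a percentage of the wild-type percent bound.

    May exceed 100 when a mutant binds better than wild type.
    """
    if p_wt <= 0:
        raise ValueError("wild-type percent bound must be > 0")
    if p_mut < 0:
        raise ValueError("percent bound must be >= 0")
    return 100.0 * p_mut / p_wt


# ---------------------------------------------------------------------------
# Loss classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LossCall:
    """Per mutant x partner binding-loss classification.

    ``category`` is the highest loss threshold strictly exceeded
    (``">70"``, ``">50"``, ``">25"``) or ``"none"``.  ``specific`` is True
    when this is the mutant's only partner with any loss call.
    """

    mutant: str
    partner: str
    relative: float
    loss: float
    category: str
    specific: bool = False


def _loss_category(loss: float,
                   thresholds: Sequence[float] = LOSS_THRESHOLDS) -> str:
    cat = "none"
    for t in sorted(thresholds):
        if loss > t:
            cat = f">{t:g}"
    return cat


def classify_losses(
    screen: pd.DataFrame,
    thresholds: Sequence[float] = LOSS_THRESHOLDS,
    wt_label: str = "WT",
) -> list[LossCall]:
    """Classify binding losses from a mutant screen table.

    ``screen`` has columns ``mutant``, ``partner``, ``percent_bound``.  The
    wild-type row per partner (``wt_label``) is the normalisation reference:
    relative binding R = 100 * P_mut / P_wt, loss L = 100 - R.  Each
    mutant x partner pair is assigned the highest loss threshold it strictly
    exceeds.  A call is flagged partner-specific when the mutant loses
    binding to that partner only.
    """
    wt = screen[screen["mutant"] == wt_label]
    if wt.empty:
        raise ValueError(f"no wild-type reference rows ({wt_label!r})")
    wt_by_partner = wt.set_index("partner")["percent_bound"].to_dict()
    calls: list[LossCall] = []
    for _, row in screen[screen["mutant"] != wt_label].iterrows():
        partner = row["partner"]
        if partner not in wt_by_partner:
            raise ValueError(f"missing WT reference for partner {partner!r}")
        r = relative_binding(row["percent_bound"], wt_by_partner[partner])
        loss = 100.0 - r
        calls.append(LossCall(mutant=row["mutant"], partner=partner,
                              relative=r, loss=loss,
                              category=_loss_category(loss, thresholds)))
    # specificity: the only partner with a loss call for that mutant
    lossy: dict[str, list[int]] = {}
    for i, c in enumerate(calls):
        if c.category != "none":
            lossy.setdefault(c.mutant, []).append(i)
    out = []
    for i, c in enumerate(calls):
        specific = c.category != "none" and len(lossy.get(c.mutant, [])) == 1
        out.append(LossCall(c.mutant, c.partner, c.relative, c.loss,
                            c.category, specific))
    return out


def losses_to_frame(calls: Iterable[LossCall]) -> pd.DataFrame:
    """Tabulate loss calls (mutant, partner, R, loss, category, specific)."""
    return pd.DataFrame(
        [(c.mutant, c.partner, c.relative, c.loss, c.category, c.specific)
         for c in calls],
        columns=["mutant", "partner", "relative", "loss", "category",
                 "specific"],
    )


# ---------------------------------------------------------------------------
# Hill fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HillFit:
    """Least-squares Hill-model fit.

    ``kd`` is the half-saturation constant; it is reported as EC50 (the
    fitted curve at X = kd equals bmax/2 by construction).  ``se`` holds
    approximate parameter standard errors (NaN when not estimable).
    """

    bmax: float
    kd: float
    h: float
    rss: float
    converged: bool
    se: tuple[float, float, float] = (float("nan"),) * 3

    @property
    def ec50(self) -> float:
        return self.kd

    def predict(self, x):
        return hill_response(x, self.bmax, self.kd, self.h)


def fit_hill(data: pd.DataFrame, h_starts: Sequence[float] = (0.5, 1, 2, 4),
             n_kd_starts: int = 8) -> HillFit:
    """Fit Y = Bmax * X^h / (Kd^h + X^h) by multi-start least squares.

    ``data`` has columns ``conc_nM`` and ``response``.  Starting points are
    a log-spaced Kd grid over the nonzero concentration range crossed with
    ``h_starts`` and Bmax = max(Y); the best converged candidate by residual
    sum of squares wins.  Bounds: Bmax in (0, 10*max Y], Kd in (0, 1e4 nM],
    h in (0.1, 10].
    """
    x = np.asarray(data["conc_nM"], dtype=float)
    y = np.asarray(data["response"], dtype=float)
    if len(np.unique(x)) < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if np.allclose(y, 0):
        raise ValueError("all responses are zero; nothing to fit")
    if np.allclose(y, y[0]):
        raise ValueError("responses are constant; Hill fit is unidentified")

    xpos = x[x > 0]
    kd_grid = np.geomspace(xpos.min(), xpos.max(), n_kd_starts)
    bmax0 = float(y.max())
    lo = [1e-12, 1e-12, 0.1]
    # Kd bound covers the sampled concentration range even in unusual units
    hi = [10.0 * bmax0, max(1e4, 100.0 * float(xpos.max())), 10.0]

    best: tuple[float, np.ndarray, np.ndarray] | None = None
    converged = False
    for kd0, h0 in itertools.product(kd_grid, h_starts):
        try:
            popt, pcov = optimize.curve_fit(
                hill_response, x, y, p0=[bmax0, kd0, h0], bounds=(lo, hi),
                maxfev=10_000)
        except RuntimeError:
            continue
        rss = float(np.sum((y - hill_response(x, *popt)) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt, pcov)
            converged = True
    if best is None:  # keep the best unconverged candidate
        popt = np.array([bmax0, float(np.median(kd_grid)), 1.0])
        best = (float(np.sum((y - hill_response(x, *popt)) ** 2)),
                popt, np.full((3, 3), np.nan))
    rss, popt, pcov = best
    with np.errstate(invalid="ignore"):
        se = tuple(float(s) for s in np.sqrt(np.diag(pcov)))
    return HillFit(bmax=float(popt[0]), kd=float(popt[1]), h=float(popt[2]),
                   rss=rss, converged=converged, se=se)


# ---------------------------------------------------------------------------
# Competition profiles
# ---------------------------------------------------------------------------

def _logistic4_desc(x, top, bottom, ic50, slope):
    """Descending four-parameter logistic in log-concentration."""
    x = np.asarray(x, dtype=float)
    out = np.full_like(x, top)
    pos = x > 0
    out[pos] = bottom + (top - bottom) / (1.0 + (x[pos] / ic50) ** slope)
    return out


@dataclass(frozen=True)
class CompetitionFit:
    """Normalized competition profile and optional descending 4PL fit.

    ``inhibition`` is True when a significant monotone decreasing trend was
    detected (one-sided Spearman test); only then are the logistic
    parameters defined.  ``normalized`` has the zero-competitor bin at 100%
    by construction.
    """

    normalized: pd.DataFrame
    inhibition: bool
    trend_rho: float
    trend_p: float
    top: float = float("nan")
    bottom: float = float("nan")
    ic50: float = float("nan")
    slope: float = float("nan")


def competition_profile(data: pd.DataFrame, alpha: float = 0.05,
                        ) -> CompetitionFit:
    """Normalize a competition titration and test for inhibition.

    ``data`` has columns ``conc_nM`` (competitor) and ``response``; a
    zero-competitor bin is required and defines 100%.  A descending
    four-parameter logistic is fitted only when the Spearman rank
    correlation between concentration and signal is significantly negative;
    otherwise the verdict is "no inhibition" and IC50 is undefined (the
    isotype-control case).
    """
    x = np.asarray(data["conc_nM"], dtype=float)
    y = np.asarray(data["response"], dtype=float)
    zero = x == 0
    if not zero.any():
        raise ValueError("competition data must include a zero-competitor bin")
    ref = float(y[zero].mean())
    if ref <= 0:
        raise ValueError("zero-competitor signal must be > 0")
    norm = 100.0 * y / ref
    normalized = pd.DataFrame({"conc_nM": x, "normalized": norm})

    if np.ptp(norm) == 0:  # exactly constant signal: trivially no trend
        rho, p_two = 0.0, 1.0
    else:
        rho, p_two = stats.spearmanr(x, norm)
    p_dec = p_two / 2.0 if rho < 0 else 1.0 - p_two / 2.0
    if not (np.isfinite(rho) and rho < 0 and p_dec < alpha):
        return CompetitionFit(normalized=normalized, inhibition=False,
                              trend_rho=float(rho), trend_p=float(p_dec))

    xpos = x[x > 0]
    p0 = [100.0, float(norm.min()), float(np.median(xpos)), 1.0]
    try:
        popt, _ = optimize.curve_fit(
            _logistic4_desc, x, norm, p0=p0,
            bounds=([0, 0, 1e-9, 0.1], [200, 100, 1e6, 10]), maxfev=10_000)
    except RuntimeError:
        return CompetitionFit(normalized=normalized, inhibition=True,
                              trend_rho=float(rho), trend_p=float(p_dec))
    return CompetitionFit(normalized=normalized, inhibition=True,
                          trend_rho=float(rho), trend_p=float(p_dec),
                          top=float(popt[0]), bottom=float(popt[1]),
                          ic50=float(popt[2]), slope=float(popt[3]))


# ---------------------------------------------------------------------------
# Suppressor rescue
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RescuePair:
    """A receptor-mutant x ligand-mutant pair whose binding exceeds the
    rescue threshold (charge-reversal suppressor evidence of proximity)."""

    receptor_mutant: str
    ligand_mutant: str
    relative: float


def suppressor_rescue(
    matrix: pd.DataFrame,
    rescue_threshold: float = 50.0,
    loss_threshold: float = 50.0,
    wt_label: str = "WT",
) -> list[RescuePair]:
    """Find suppressor rescues in a receptor-mutant x ligand-mutant matrix.

    ``matrix`` is indexed by receptor mutants (rows, e.g. K/H charge
    reversals) with ligand mutants as columns (e.g. D/E charge mutants);
    cells are relative binding in % of the WT:WT pair (which must be
    present and is the 100% reference).  A pair rescues when its cell
    exceeds ``rescue_threshold`` while the ligand mutant alone (vs the WT
    receptor row) has lost binding (relative below ``100 - loss_threshold``).
    """
    if wt_label not in matrix.index or wt_label not in matrix.columns:
        raise ValueError("matrix must contain a WT row and WT column")
    if (np.asarray(matrix, dtype=float) < 0).any():
        raise ValueError("binding matrix cells must be >= 0")
    pairs: list[RescuePair] = []
    for col in matrix.columns:
        if col == wt_label:
            continue
        if matrix.loc[wt_label, col] >= 100.0 - loss_threshold:
            continue  # ligand mutant alone retains binding: rescue undefined
        for row in matrix.index:
            if row == wt_label:
                continue
            val = float(matrix.loc[row, col])
            if val > rescue_threshold:
                pairs.append(RescuePair(receptor_mutant=row,
                                        ligand_mutant=col, relative=val))
    return pairs
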