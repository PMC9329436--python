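"""4PL viability dose-response fitting, censoring, and SAR fold arithmetic.

Viability is modelled with the four-parameter logistic

    y(c) = bottom + (top − bottom) / (1 + 10^((log10(IC50) − log10(c)) · hill))

fit by multi-start least squares on replicate viability fractions
(normalised so the vehicle-control mean ≈ 1).  An inactive compound whose
curve never reaches the midpoint inside the tested range is censored and
rendered with the "> 100" (top-concentration) convention used throughout
the SAR tables; fold-change and selectivity-index arithmetic propagates
censoring as one-sided bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .errors import IndeterminateFoldError, InsufficientDataError


def four_param_logistic(c, log_ic50, hill, top, bottom):
    """Evaluate the 4PL at concentrations ``c`` (µM)."""
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ic50 - np.log10(c)) * hill))


class FourParamLogistic(BaseEstimator, RegressorMixin):
    """Multi-start 4PL least-squares fit with range censoring.

    Parameters
    ----------
    n_starts : int
        Number of log-spaced IC50 initialisations across the tested range.
    bottom_min : float
        Lower bound on the bottom asymptote (viability cannot be negative).
    top_max : float
        Upper bound for both asymptotes, in control-normalised units.

    Fitted attributes: ``ic50_`` (µM), ``hill_``, ``top_``, ``bottom_``,
    ``censored_``, ``rss_``, ``n_points_``, ``flags_``.  The parameters are
    normalised so ``top_ ≥ bottom_``; a decreasing (inhibition) response
    then has ``hill_ < 0`` and an increasing response is flagged.
    """

    def __init__(self, n_starts=7, bottom_min=0.0, top_max=10.0, max_nfev=2000):
        self.n_starts = n_starts
        self.bottom_min = bottom_min
        self.top_max = top_max
        self.max_nfev = max_nfev

    def fit(self, concentrations, responses):
        c = np.asarray(concentrations, dtype=float).ravel()
        y = np.asarray(responses, dtype=float)
        if y.ndim == 2:  # replicate columns share the concentration vector
            c = np.repeat(c, y.shape[1])
            y = y.ravel()
        if not (np.isfinite(c).all() and np.isfinite(y).all()):
            raise ValueError("concentrations and responses must be finite")
        if np.any(c <= 0):
            raise ValueError("concentrations must be positive")
        if len(np.unique(c)) < 4:
            raise InsufficientDataError(
                "a 4PL fit needs at least 4 distinct concentrations")

        lc, hc = np.log10(c.min()), np.log10(c.max())
        ymin, ymax = float(y.min()), float(y.max())
        spread = max(ymax - ymin, 1e-6)

        def resid(p):
            return four_param_logistic(c, *p) - y

        lb = [lc - 3.0, -10.0, self.bottom_min, self.bottom_min]
        ub = [hc + 3.0, 10.0, self.top_max, self.top_max]
        best = None
        for start_lic50 in np.linspace(lc, hc, self.n_starts):
            for hill0 in (-1.0, 1.0):
                p0 = [start_lic50, hill0,
                      np.clip(ymax, self.bottom_min + 1e-3, self.top_max),
                      np.clip(ymin, self.bottom_min, self.top_max - 1e-3)]
                try:
                    sol = least_squares(resid, p0, bounds=(lb, ub),
                                        xtol=1e-13, ftol=1e-13, gtol=1e-13,
                                        max_nfev=self.max_nfev)
                except Exception:
                    continue
                if not sol.success:
                    continue
                rss = float(np.sum(sol.fun**2))
                # ties in RSS break to the lower IC50
                if (best is None or rss < best[0] - 1e-12
                        or (abs(rss - best[0]) <= 1e-12
                            and sol.x[0] < best[1].x[0])):
                    best = (rss, sol)

        self.n_points_ = len(c)
        self.flags_ = []
        if best is None:
            self._set_censored(np.nan, np.nan, ymax, ymin, np.nan, hc)
            self.flags_.append("fit did not converge")
            return self
        rss, sol = best
        log_ic50, hill, top, bottom = sol.x
        if top < bottom:  # (hill, top, bottom) ↔ (−hill, bottom, top) redundancy
            top, bottom, hill = bottom, top, -hill
        ic50 = 10.0 ** log_ic50
        top_conc = c.max()

        # Half-maximal inhibition must be reached inside the tested range:
        # the fitted curve has to fall to half the control plateau (top/2).
        # For a full-amplitude curve (bottom = 0) this is exactly the
        # asymptote midpoint; for shallow dips it censors, matching the
        # tables' "> top" convention.  The 4PL is monotone in c, so the
        # range extrema are at the endpoints.
        y_lo = float(four_param_logistic(c.min(), log_ic50, hill, top, bottom))
        y_hi = float(four_param_logistic(top_conc, log_ic50, hill, top, bottom))
        reaches_half = min(y_lo, y_hi) <= top / 2.0
        censored = (ic50 > top_conc) or not reaches_half

        self.ic50_ = float(ic50)
        self.hill_ = float(hill)
        self.top_ = float(top)
        self.bottom_ = float(bottom)
        self.rss_ = rss
        self.censored_ = bool(censored)
        self.top_concentration_ = float(top_conc)
        if y_hi > y_lo + 0.1 * spread:
            self.flags_.append("response increases with concentration")
        if not censored and ic50 < c.min():
            self.flags_.append("IC50 below tested range")
        return self

    def _set_censored(self, ic50, hill, top, bottom, rss, log_top_conc):
        self.ic50_ = ic50
        self.hill_ = hill
        self.top_ = top
        self.bottom_ = bottom
        self.rss_ = rss
        self.censored_ = True
        self.top_concentration_ = 10.0 ** log_top_conc

    def predict(self, concentrations):
        check_is_fitted(self, "ic50_")
        return four_param_logistic(np.asarray(concentrations, dtype=float).ravel(),
                                   np.log10(self.ic50_), self.hill_,
                                   self.top_, self.bottom_)


def _sig2(v: float) -> str:
    """Two-significant-figure table rendering (the SAR tables' style)."""
    if not np.isfinite(v):
        return "nan"
    return f"{float(f'{v:.2g}'):g}"


@dataclass
class ViabilityFit:
    """A 4PL fit result for one (compound, cell line) pair."""

    compound_id: str
    cell_line: str
    ic50: float          # µM; meaningful only when not censored
    hill: float
    top: float
    bottom: float
    censored: bool
    rss: float
    n_points: int
    top_concentration: float
    flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def ic50_text(self) -> str:
        if self.censored:
            return f"> {_sig2(self.top_concentration)}"
        return _sig2(self.ic50)


def fit_4pl(concentrations, responses, *, compound_id: str = "",
            cell_line: str = "", **estimator_kwargs) -> ViabilityFit:
    """Fit a 4PL to replicate viability fractions; see :class:`FourParamLogistic`."""
    est = FourParamLogistic(**estimator_kwargs).fit(concentrations, responses)
    return ViabilityFit(
        compound_id=compound_id, cell_line=cell_line,
        ic50=est.ic50_, hill=est.hill_, top=est.top_, bottom=est.bottom_,
        censored=est.censored_, rss=est.rss_, n_points=est.n_points_,
        top_concentration=est.top_concentration_, flags=tuple(est.flags_))


# ---- fold-change / selectivity arithmetic ------------------------------

@dataclass(frozen=True)
class FoldChange:
    """A fold ratio, possibly a one-sided bound from a censored IC50."""

    value: float
    bound: str | None = None  # None, ">" (at least) or "<" (at most)

    @property
    def text(self) -> str:
        v = f"{float(f'{self.value:.3g}'):g}"
        return v if self.bound is None else f"{self.bound} {v}"

    @property
    def nearest_int(self) -> int:
        """Nearest-integer rendering for prose claims ('25-fold drop')."""
        return round(self.value)

    def prose(self) -> str:
        base = f"{self.nearest_int}-fold"
        return base if self.bound is None else f"{self.bound} {base}"


def _as_ic50(entry) -> tuple[float, bool]:
    """Normalise a fold-change operand to (value µM, censored-above?)."""
    if isinstance(entry, ViabilityFit):
        if entry.censored:
            return entry.top_concentration, True
        return entry.ic50, False
    if isinstance(entry, str):
        s = entry.strip()
        if s.startswith(">"):
            return float(s[1:].strip()), True
        return float(s), False
    v = float(entry)
    if v <= 0:
        raise ValueError("IC50 values must be positive")
    return v, False


def fold_change(numerator, denominator) -> FoldChange:
    """numerator / denominator with censored-bound propagation.

    A censored numerator "> C" gives a lower bound "> C/denominator"; a
    censored denominator gives an upper bound.  Two censored operands are
    indeterminate.
    """
    a, a_cens = _as_ic50(numerator)
    b, b_cens = _as_ic50(denominator)
    if a_cens and b_cens:
        raise IndeterminateFoldError(
            "both IC50s are censored; the fold change is indeterminate")
    if a_cens:
        return FoldChange(value=a / b, bound=">")
    if b_cens:
        return FoldChange(value=a / b, bound="<")
    return FoldChange(value=a / b)


def selectivity_index(toxicity, efficacy) -> FoldChange:
    """Toxicity IC50 (control line, e.g. WS1 fibroblasts) over efficacy
    IC50 (disease line); values > 1 indicate a therapeutic window."""
    return fold_change(toxicity, efficacy)


def build_sar_table(fits: list[ViabilityFit],
                    layout: tuple[list[str], list[str]] | None = None) -> pd.DataFrame:
    """Compound × cell-line IC50 table with "> 100"-style censored entries."""
    if not fits:
        return pd.DataFrame()
    if layout is None:
        compounds = list(dict.fromkeys(f.compound_id for f in fits))
        lines = list(dict.fromkeys(f.cell_line for f in fits))
    else:
        compounds, lines = [list(v) for v in layout]
    table = pd.DataFrame(index=compounds, columns=lines, dtype=object)
    table.index.name = "compound_id"
    for f in fits:
        table.loc[f.compound_id, f.cell_line] = f.ic50_text
    return table
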