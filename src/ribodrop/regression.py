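"""Exponential drop-off model fit and its inferential statistics.

The mean normalized ribosome density per bin is modelled as an exponential
decay in the bin number,

    Y = A * exp(-r_b * X),

so regressing ln(Y) on X by weighted least squares gives a slope whose
negative is the drop-off rate per bin, r_b.  A bin of l nucleotides spans
l_c = l/3 codons; the per-codon rate follows from the complement rule

    r_c = 1 - (1 - r_b)^(1/l_c),

i.e. surviving a whole bin means surviving each of its l_c codons.

The standard error of the slope uses the classical simple-regression
formula

    S_E = sqrt( sum (y_i - yhat_i)^2 / (N - 2) ) / sqrt( sum (x_i - xbar)^2 )

generalised with the regression weights (weighted residual sum of squares,
weighted x-variance about the weighted mean); with equal weights it reduces
exactly to the unweighted formula.  From S_E follow the margin of error
M_E = t_{alpha/2} * S_E on N-2 degrees of freedom, the confidence interval
r_b +/- M_E, and the slope t-test t = r_b / S_E with a one-sided p-value
(alternative: r_b > 0).  Goodness of fit is summarised by the RMSE of the
log-scale residuals and a weighted R^2.

Two fitted datasets are compared with Welch's statistic

    t = (r_b1 - r_b2) / sqrt(SE_1^2 + SE_2^2)

referred to a standard normal (the large-degrees-of-freedom limit; see the
methods note for why the normal reference and a one-sided tail are the
defaults).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .binning import DensityVector

__all__ = [
    "DropoffEstimate",
    "ComparisonResult",
    "fit_dropoff",
    "standard_error",
    "confidence_interval",
    "slope_t_test",
    "goodness_of_fit",
    "per_codon_rate",
    "welch_compare",
    "survival_probability",
]


@dataclass
class DropoffEstimate:
    """Fitted drop-off rate and the full set of fit statistics.

    ``r_b`` is a probability per bin, ``r_c`` per codon; ``A`` is the fitted
    intercept on the natural scale (of no biological interest).  ``degenerate``
    flags fits where the inferential statistics are not meaningful (flat
    density, or an exactly perfect fit with a nonzero slope).
    """

    r_b: float
    r_c: float
    A: float
    bin_size_nt: int
    se: float
    margin_of_error: float
    ci: tuple[float, float]
    t_score: float
    p_value: float
    rmse: float
    r_squared: float
    n_bins_used: int
    alpha: float = 0.05
    degenerate: bool = False

    @property
    def l_c(self) -> float:
        """Bin length in codons (real-valued)."""
        return self.bin_size_nt / 3.0


@dataclass
class ComparisonResult:
    """Welch comparison between two fitted drop-off rates."""

    t_score: float
    p_value: float
    tail: str
    inputs: tuple[float, float, float, float]   # (r_b1, se1, r_b2, se2)


def _weighted_slope_intercept(x: np.ndarray, y: np.ndarray,
                              w: np.ndarray) -> tuple[float, float]:
    """Closed-form weighted least squares line fit."""
    wsum = w.sum()
    xbar = (w * x).sum() / wsum
    ybar = (w * y).sum() / wsum
    sxx = (w * (x - xbar) ** 2).sum()
    if sxx <= 0:
        raise ValueError("degenerate design: zero weighted x-variance")
    slope = (w * (x - xbar) * (y - ybar)).sum() / sxx
    intercept = ybar - slope * xbar
    return slope, intercept


def standard_error(residuals: np.ndarray, x: np.ndarray,
                   weights: np.ndarray | None = None) -> float:
    """Standard error of the regression slope.

    Weighted analog of the classical formula; equal weights reduce exactly
    to the unweighted expression.  ``N`` is the number of points used.
    """
    residuals = np.asarray(residuals, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError(f"standard error needs N >= 3 points, got {n}")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    wsum = w.sum()
    xbar = (w * x).sum() / wsum
    sxx = (w * (x - xbar) ** 2).sum()
    if sxx <= 0:
        raise ValueError("degenerate design: zero weighted x-variance")
    # the overall weight scale cancels between numerator and denominator
    s2 = (w * residuals ** 2).sum() / (n - 2)
    return float(np.sqrt(s2) / np.sqrt(sxx))


def confidence_interval(r_b: float, se: float, n: int,
                        alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Margin of error and CI for the drop-off rate at level 1 - alpha.

    Uses the upper alpha/2 quantile of Student's t with N - 2 degrees of
    freedom.
    """
    if n < 3:
        raise ValueError(f"confidence interval needs N >= 3, got {n}")
    t_crit = float(stats.t.ppf(1.0 - alpha / 2.0, df=n - 2))
    margin = t_crit * se
    return margin, (r_b - margin, r_b + margin)


def slope_t_test(r_b: float, se: float, n: int) -> tuple[float, float]:
    """t-score and one-sided p-value for H0: r_b = 0 vs H1: r_b > 0.

    ``se == 0`` with a nonzero rate is a degenerate (exact) fit: the test
    returns (inf, 0.0); a flat fit (r_b == 0) returns p = 0.5.
    """
    if se == 0:
        if r_b == 0:
            return 0.0, 0.5
        return float(np.inf) * np.sign(r_b), 0.0
    t = r_b / se
    p = float(stats.t.sf(t, df=n - 2))
    return float(t), p


def goodness_of_fit(observed: np.ndarray, fitted: np.ndarray,
                    weights: np.ndarray | None = None) -> tuple[float, float]:
    """RMSE (unweighted, on the fit's own scale) and weighted R^2."""
    observed = np.asarray(observed, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    n = len(observed)
    if n < 3:
        raise ValueError("goodness of fit needs >= 3 points")
    resid = observed - fitted
    rmse = float(np.sqrt((resid ** 2).sum() / n))
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    ybar = (w * observed).sum() / w.sum()
    sst = (w * (observed - ybar) ** 2).sum()
    ssr = (w * resid ** 2).sum()
    r2 = 1.0 if sst == 0 and ssr == 0 else (0.0 if sst == 0 else 1.0 - ssr / sst)
    return rmse, float(r2)


def per_codon_rate(r_b: float, bin_size_nt: int) -> float:
    """Convert a per-bin rate to a per-codon rate.

    ``l_c = bin_size_nt / 3`` codons per bin (real-valued);
    ``r_c = 1 - (1 - r_b)^(1/l_c)``.
    """
    if r_b >= 1:
        raise ValueError(f"per-bin rate must be < 1, got {r_b}")
    if bin_size_nt < 3:
        raise ValueError(f"bin size must be >= 3 nt, got {bin_size_nt}")
    l_c = bin_size_nt / 3.0
    return float(1.0 - (1.0 - r_b) ** (1.0 / l_c))


def fit_dropoff(density: DensityVector, alpha: float = 0.05) -> DropoffEstimate:
    """Fit the exponential decay to a density vector.

    Weighted least squares of ln(Y) on X over the included bins, with the
    density's regression weights.  All statistics (SE, CI, t, p, RMSE, R^2)
    are computed over the same included bins; N in the formulas is their
    count.  A flat density returns r_b = 0 with p = 0.5 rather than failing.
    """
    mask = density.included
    n = int(np.count_nonzero(mask))
    if n < 3:
        raise ValueError(f"need >= 3 usable bins for the fit, got {n}")
    x = density.X[mask].astype(float)
    y = np.log(density.Y[mask])
    w = density.weights[mask].astype(float)

    slope, intercept = _weighted_slope_intercept(x, y, w)
    r_b = -slope
    fitted = intercept + slope * x
    resid = y - fitted
    se = standard_error(resid, x, w)
    margin, ci = confidence_interval(r_b, se, n, alpha)
    t_score, p_value = slope_t_test(r_b, se, n)
    rmse, r2 = goodness_of_fit(y, fitted, w)
    degenerate = bool(se == 0 or np.allclose(y, y[0]))
    # a fitted decay steeper than one event per bin leaves the probability
    # model's domain; the per-bin rate is still reported, the conversion is not
    r_c = (per_codon_rate(float(r_b), density.bin_size_nt)
           if r_b < 1 else float("nan"))
    return DropoffEstimate(
        r_b=float(r_b),
        r_c=r_c,
        A=float(np.exp(intercept)),
        bin_size_nt=density.bin_size_nt,
        se=se,
        margin_of_error=float(margin),
        ci=(float(ci[0]), float(ci[1])),
        t_score=float(t_score),
        p_value=float(p_value),
        rmse=rmse,
        r_squared=r2,
        n_bins_used=n,
        alpha=alpha,
        degenerate=degenerate,
    )


def welch_compare(est1: DropoffEstimate, est2: DropoffEstimate,
                  tail: str = "one_sided") -> ComparisonResult:
    """Welch's test between two fitted drop-off rates.

    The p-value is referred to a standard normal (the per-dataset degrees
    of freedom are large; a Welch-Satterthwaite correction would need the
    per-group sizes and changes nothing at this scale).  ``one_sided``
    returns P(Z >= |t|); ``two_sided`` doubles it.
    """
    if tail not in ("one_sided", "two_sided"):
        raise ValueError(f"tail must be 'one_sided' or 'two_sided', got {tail!r}")
    r1, s1, r2, s2 = est1.r_b, est1.se, est2.r_b, est2.se
    if s1 <= 0 or s2 <= 0:
        raise ValueError("Welch comparison requires positive standard errors")
    t = (r1 - r2) / np.hypot(s1, s2)
    p = float(stats.norm.sf(abs(t)))
    if tail == "two_sided":
        p = min(1.0, 2.0 * p)
    if t == 0 and tail == "two_sided":
        p = 1.0
    return ComparisonResult(t_score=float(t), p_value=p, tail=tail,
                            inputs=(r1, s1, r2, s2))


def survival_probability(r_c: float, length_codons: float,
                         mode: str = "exact") -> float:
    """Probability that a ribosome reaches the stop codon of an L-codon CDS.

    ``exact`` evaluates (1 - r_c)^L; ``exponential`` the small-rate limit
    exp(-r_c * L).
    """
    if not 0 <= r_c < 1:
        raise ValueError(f"per-codon rate must be in [0, 1), got {r_c}")
    if length_codons < 0:
        raise ValueError(f"CDS length must be >= 0, got {length_codons}")
    if mode == "exact":
        return float((1.0 - r_c) ** length_codons)
    if mode == "exponential":
        return float(np.exp(-r_c * length_codons))
    raise ValueError(f"mode must be 'exact' or 'exponential', got {mode!r}")
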