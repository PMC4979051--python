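"""Null distribution of the median of n i.i.d. Student-t variates.

For odd n the sample median is the central order statistic and its density
has the closed form

    g(t) = C_n [F(t)]^((n-1)/2) [1 - F(t)]^((n-1)/2) f(t),
    C_n  = n! / (((n-1)/2)!)^2,

with F and f the Student-t cdf and pdf. Its cdf is the regularized
incomplete beta function I_{F(t)}(k, k) with k = (n+1)/2, which we use
instead of quadrature because it is exact and vectorizes.

For even n the analogous expression with exponents n/2 and constant
n!/((n/2)!)^2 does NOT integrate to one (total mass 1/3 at n = 2; see
:func:`printed_even_median_t_pdf`, kept for documentation). The sample
median used throughout this package for even n is the mean of the two
central order statistics X_(k), X_(k+1) with k = n/2, whose joint density

    c F(x)^(k-1) [1 - F(y)]^(k-1) f(x) f(y),  x < y,  c = n!/((k-1)!)^2

yields, after the substitution x = m - u, y = m + u,

    g(m) = 2 c ∫_0^∞ F(m-u)^(k-1) [1-F(m+u)]^(k-1) f(m-u) f(m+u) du

and the single-integral cdf

    G(t) = (c/k) ∫_{-∞}^t F(x)^(k-1) f(x)
                 [ (1-F(x))^k - (1-F(2t-x))^k ] dx ,

both evaluated by adaptive quadrature. Both densities are symmetric about
zero, so G(0) = 1/2 and G(t) + G(-t) = 1.

Probes of one gene are treated as independent draws from the same t
distribution; this i.i.d. assumption is stated, not corrected for.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from scipy import integrate, special
from scipy.interpolate import PchipInterpolator

from .errors import DomainError

__all__ = [
    "MedianTDistribution",
    "median_t_pdf",
    "median_t_cdf",
    "p_value",
    "median_t_mc_oracle",
    "printed_even_median_t_pdf",
    "get_median_t_distribution",
]


class MedianTDistribution:
    """Distribution of the median of ``n`` i.i.d. Student-t(df) variates.

    Parameters
    ----------
    n
        Number of variates (probes of a gene), >= 1.
    df
        Degrees of freedom of the underlying t distribution, >= 1.
    """

    def __init__(self, n: int, df: float):
        if n < 1 or int(n) != n:
            raise DomainError(f"n must be a positive integer, got {n}")
        if df < 1:
            raise DomainError(f"df must be >= 1, got {df}")
        self.n = int(n)
        self.df = float(df)
        if self.n % 2 == 1:
            self._k = (self.n + 1) // 2  # rank of the central order statistic
            self.C_n = math.factorial(self.n) // math.factorial((self.n - 1) // 2) ** 2
        else:
            self._k = self.n // 2
            # exact constant of the joint density of the two central order stats
            self.C_n = math.factorial(self.n) // math.factorial(self._k - 1) ** 2
        # log-pdf constant of the Student t
        self._log_f_const = (
            special.gammaln((self.df + 1) / 2.0)
            - special.gammaln(self.df / 2.0)
            - 0.5 * math.log(self.df * math.pi)
        )
        self._even_interp: PchipInterpolator | None = None
        self._even_grid: np.ndarray | None = None

    # -- underlying Student t ------------------------------------------

    def _t_cdf(self, x):
        return special.stdtr(self.df, x)

    def _t_logpdf(self, x):
        x = np.asarray(x, dtype=float)
        return self._log_f_const - (self.df + 1) / 2.0 * np.log1p(x * x / self.df)

    def _t_pdf(self, x):
        return np.exp(self._t_logpdf(x))

    # -- pdf ------------------------------------------------------------

    def pdf(self, t):
        """Density g(t) of the median; accepts scalars or arrays."""
        t_arr = np.asarray(t, dtype=float)
        if self.n % 2 == 1:
            out = self._odd_pdf(t_arr)
        else:
            out = np.vectorize(self._even_pdf_scalar, otypes=[float])(t_arr)
        return out if t_arr.ndim else float(out)

    def _odd_pdf(self, t: np.ndarray) -> np.ndarray:
        if self.n == 1:
            return self._t_pdf(t)
        m = self._k - 1  # = (n-1)/2
        F = self._t_cdf(t)
        with np.errstate(divide="ignore"):
            logterm = m * (np.log(F) + np.log1p(-F))
        out = np.where(
            (F > 0.0) & (F < 1.0),
            math.log(self.C_n) + logterm + self._t_logpdf(t),
            -np.inf,
        )
        return np.exp(out)

    def _even_pdf_scalar(self, m: float) -> float:
        k = self._k
        c = float(self.C_n)

        def integrand(u: float) -> float:
            lo, hi = m - u, m + u
            F_lo = self._t_cdf(lo)
            S_hi = special.stdtr(self.df, -hi)  # 1 - F(hi), accurate in the tail
            if F_lo <= 0.0 or S_hi <= 0.0:
                return 0.0
            log_val = (
                (k - 1) * (math.log(F_lo) + math.log(S_hi))
                + float(self._t_logpdf(lo))
                + float(self._t_logpdf(hi))
            )
            return math.exp(log_val)

        # the integrand peaks near u = |m| (where m - u or m + u crosses 0);
        # split there so adaptive quadrature cannot miss a remote peak
        edges = sorted({0.0, max(0.0, abs(m) - 30.0), abs(m) + 30.0})
        val = 0.0
        for lo_u, hi_u in zip(edges, edges[1:]):
            val += integrate.quad(
                integrand, lo_u, hi_u, epsabs=1e-13, epsrel=1e-10, limit=300
            )[0]
        val += integrate.quad(
            integrand, edges[-1], np.inf, epsabs=1e-13, epsrel=1e-10, limit=300
        )[0]
        return 2.0 * c * val

    # -- cdf ------------------------------------------------------------

    def cdf(self, t):
        """G(t) = P(median <= t); exact for odd n, quadrature for even n."""
        t_arr = np.asarray(t, dtype=float)
        if self.n % 2 == 1:
            out = special.betainc(self._k, self._k, self._t_cdf(t_arr))
        elif t_arr.size > 64:
            out = self._even_cdf_interp(t_arr)
        else:
            out = np.vectorize(self._even_cdf_scalar, otypes=[float])(t_arr)
        return out if t_arr.ndim else float(out)

    def _even_cdf_scalar(self, t: float) -> float:
        if not math.isfinite(t):
            return 0.0 if t < 0 else 1.0
        k = self._k
        c = float(self.C_n)

        def integrand(x: float) -> float:
            F_x = self._t_cdf(x)
            if F_x <= 0.0:
                return 0.0
            S_x = special.stdtr(self.df, -x)
            S_ref = special.stdtr(self.df, -(2.0 * t - x))
            bracket = S_x**k - S_ref**k
            if bracket <= 0.0:
                return 0.0
            return F_x ** (k - 1) * float(self._t_pdf(x)) * bracket

        # split around the bulk so a remote upper limit cannot hide the peak
        pts = [x for x in (-30.0, 0.0, 30.0) if x < t]
        edges = [-np.inf] + pts + [t]
        val = 0.0
        for lo_x, hi_x in zip(edges, edges[1:]):
            val += integrate.quad(
                integrand, lo_x, hi_x, epsabs=1e-12, epsrel=1e-10, limit=300
            )[0]
        return min(max(c / k * val, 0.0), 1.0)

    def _build_even_interp(self) -> None:
        qs = np.linspace(1e-9, 1.0 - 1e-9, 513)
        grid = special.stdtrit(self.df, qs)
        G = np.array([self._even_cdf_scalar(x) for x in grid])
        G = np.maximum.accumulate(np.clip(G, 0.0, 1.0))
        keep = np.concatenate([[True], np.diff(grid) > 0])
        self._even_grid = grid[keep]
        self._even_interp = PchipInterpolator(self._even_grid, G[keep])

    def _even_cdf_interp(self, t: np.ndarray) -> np.ndarray:
        if self._even_interp is None:
            self._build_even_interp()
        assert self._even_interp is not None and self._even_grid is not None
        out = np.empty_like(t, dtype=float)
        lo, hi = self._even_grid[0], self._even_grid[-1]
        below, above = t < lo, t > hi
        inside = ~(below | above)
        out[below] = 0.0
        out[above] = 1.0
        out[inside] = np.clip(self._even_interp(t[inside]), 0.0, 1.0)
        return out

    # -- p-values --------------------------------------------------------

    def p_value(self, t_m: float, sided: str = "two") -> float:
        """p-value of an observed median t.

        ``sided="one"`` returns the lower-tail mass G(t_m); the default
        ``sided="two"`` returns 2 * min(G(t_m), 1 - G(t_m)), clamped to
        [0, 1]. Infinite sentinels give p = 0 (two-sided) or the
        corresponding tail limit (one-sided).
        """
        if sided not in ("one", "two"):
            raise DomainError(f"sided must be 'one' or 'two', got {sided!r}")
        if math.isinf(t_m):
            if sided == "two":
                return 0.0
            return 0.0 if t_m < 0 else 1.0
        G = float(self.cdf(t_m))
        if sided == "one":
            return min(max(G, 0.0), 1.0)
        return min(max(2.0 * min(G, 1.0 - G), 0.0), 1.0)

    def p_values(self, t_m, sided: str = "two") -> np.ndarray:
        """Vectorized :meth:`p_value` over an array of median t values."""
        if sided not in ("one", "two"):
            raise DomainError(f"sided must be 'one' or 'two', got {sided!r}")
        t_arr = np.asarray(t_m, dtype=float)
        finite = np.isfinite(t_arr)
        G = np.empty_like(t_arr)
        G[finite] = np.asarray(self.cdf(t_arr[finite]), dtype=float)
        G[~finite] = np.where(t_arr[~finite] < 0, 0.0, 1.0)
        if sided == "one":
            return np.clip(G, 0.0, 1.0)
        p = 2.0 * np.minimum(G, 1.0 - G)
        p[~finite] = 0.0
        return np.clip(p, 0.0, 1.0)

    def __repr__(self) -> str:  # pragma: no cover
        return f"MedianTDistribution(n={self.n}, df={self.df})"


# -- module-level operations -------------------------------------------------


def median_t_pdf(dist: MedianTDistribution, t):
    return dist.pdf(t)


def median_t_cdf(dist: MedianTDistribution, t):
    return dist.cdf(t)


def p_value(dist: MedianTDistribution, t_m: float, sided: str = "two") -> float:
    return dist.p_value(t_m, sided=sided)


def median_t_mc_oracle(
    n: int, df: float, n_draws: int, seed: int
) -> np.ndarray:
    """Monte-Carlo sample of medians of n i.i.d. Student-t(df) variates."""
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    draws = rng.standard_t(df, size=(int(n_draws), int(n)))
    return np.median(draws, axis=1)


def printed_even_median_t_pdf(n: int, df: float, t):
    """The even-n expression C_n F^(n/2) (1-F)^(n/2) f as printed.

    Kept for documentation only: it is not a probability density (at
    n = 2 its total mass is 1/3). Use :class:`MedianTDistribution` for
    the corrected even-n density.
    """
    if n < 2 or n % 2 != 0:
        raise DomainError(f"n must be a positive even integer, got {n}")
    dist = MedianTDistribution(1, df)  # borrow its Student-t helpers
    C = math.factorial(n) / math.factorial(n // 2) ** 2
    t_arr = np.asarray(t, dtype=float)
    F = dist._t_cdf(t_arr)
    out = C * F ** (n // 2) * (1.0 - F) ** (n // 2) * dist._t_pdf(t_arr)
    return out if t_arr.ndim else float(out)


@lru_cache(maxsize=256)
def get_median_t_distribution(n: int, df: float) -> MedianTDistribution:
    """Cached distribution per (n, df); genes sharing a probe count share it."""
    return MedianTDistribution(n, df)
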