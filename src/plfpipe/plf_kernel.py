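"""Per-site phylogenetic likelihood kernel with rescaling and log bookkeeping.

For every alignment site the kernel combines the two children's
conditional likelihoods through the edge transition matrices::

    clP[s] = (sum_x P_l[s, x] clL[x]) * (sum_y P_r[s, y] clR[y])

then rescales the four-entry column by its maximum, stores the log of the
scaler (``scP``), accumulates it into the cumulative log-scaler buffer
(``lnScaler``) and, at the root, folds everything into the weighted tree
log-likelihood::

    lnL = sum_k w[k] * (lnScaler[k] + ln(sum_s pi[s] clP[k, s]))

Two numeric modes are supported.  ``exact`` computes in double precision
with the true natural log and serves as the reference.  ``device``
reproduces the single-precision hardware datapath: every individual
add/mul/div result is rounded to IEEE-754 binary32 before reuse and the
natural log is the 16-segment polynomial of :mod:`plfpipe.log_approx`.
The device path performs its operations in exactly the order of the
normative data-flow graph (chained sums, a 3-comparison max chain, the
power-chain polynomial), so its outputs agree bit for bit with the
data-flow-graph interpreter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .log_approx import LogApproxTable, approx_ln, fit_log_table

__all__ = [
    "NumericMode",
    "PartialsTable",
    "TransitionMatrix",
    "StateFrequencies",
    "PatternWeights",
    "ScaleBuffers",
    "DegenerateSiteError",
    "ValidationError",
    "default_log_table",
    "compute_site_partials",
    "rescale_site",
    "update_partials_node",
    "root_log_likelihood",
    "write_partials",
    "read_partials",
]

N_STATES = 4


class ValidationError(ValueError):
    """Input violates a kernel precondition (non-finite, wrong shape...)."""


class DegenerateSiteError(ArithmeticError):
    """A site's likelihood column collapsed to all zeros (or the root dot
    product is not positive): the fixed-point of the rescaling design has
    no recovery path for this, so it is surfaced as an error."""


class NumericMode(str, Enum):
    EXACT = "exact"
    DEVICE = "device"

    @property
    def dtype(self):
        return np.float64 if self is NumericMode.EXACT else np.float32


_DEFAULT_TABLE: LogApproxTable | None = None


def default_log_table() -> LogApproxTable:
    """The package-wide segmented-log table (built once, deterministic)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = fit_log_table()
    return _DEFAULT_TABLE


def _ln(x, mode: NumericMode, table: LogApproxTable | None):
    # mode fixes the arithmetic precision; the log flavour is the true ln
    # unless a segment table is in play (always, in device mode; in exact
    # mode only when one is passed explicitly, which evaluates the
    # segmented algorithm at double precision)
    if table is not None:
        return approx_ln(x, table, device=(mode is NumericMode.DEVICE))
    if mode is NumericMode.EXACT:
        return np.log(x)
    return approx_ln(x, default_log_table(), device=True)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PartialsTable:
    """(n_sites, 4) conditional likelihoods at one node."""

    values: np.ndarray
    role: str = "internal"  # tip | internal | root

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.shape[1] != N_STATES:
            raise ValidationError("partials must have shape (n_sites, 4)")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValidationError("partials must be finite and non-negative")
        if self.role not in ("tip", "internal", "root"):
            raise ValidationError(f"unknown partials role {self.role!r}")

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]


@dataclass
class TransitionMatrix:
    """4x4 table of P(child state x | parent state s, t), rows = parent s."""

    p: np.ndarray

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=np.float64)
        if self.p.shape != (N_STATES, N_STATES):
            raise ValidationError("transition matrix must be 4x4")
        if not np.all(np.isfinite(self.p)):
            raise ValidationError("transition matrix entries must be finite")
        if np.any(self.p < 0) or np.any(self.p > 1):
            raise ValidationError("transition matrix entries must lie in [0, 1]")


@dataclass
class StateFrequencies:
    """Equilibrium base frequencies pi (A, C, G, T)."""

    pi: np.ndarray

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=np.float64)
        if self.pi.shape != (N_STATES,):
            raise ValidationError("state frequencies must be a 4-vector")
        if np.any(self.pi < 0) or abs(float(self.pi.sum()) - 1.0) > 1e-6:
            raise ValidationError("state frequencies must be non-negative and sum to 1")


@dataclass
class PatternWeights:
    """Pattern multiplicities (numSites): positive integers, one per site."""

    w: np.ndarray

    def __post_init__(self):
        self.w = np.asarray(self.w)
        if self.w.ndim != 1 or np.any(self.w < 1) or np.any(self.w != np.floor(self.w)):
            raise ValidationError("pattern weights must be integers >= 1")
        self.w = self.w.astype(np.int64)


@dataclass
class ScaleBuffers:
    """Per-site scaler bookkeeping.

    ``scP`` holds the log of the most recent node's scaler; ``lnScaler``
    is the cumulative sum of log-scalers over all nodes processed since
    the last reset (initialised to zero).
    """

    scP: np.ndarray
    lnScaler: np.ndarray

    @classmethod
    def zeros(cls, n_sites: int, mode: NumericMode = NumericMode.EXACT) -> "ScaleBuffers":
        return cls(scP=np.zeros(n_sites, dtype=mode.dtype),
                   lnScaler=np.zeros(n_sites, dtype=mode.dtype))

    def reset(self):
        self.scP[:] = 0
        self.lnScaler[:] = 0


# ---------------------------------------------------------------------------
# kernel operations (vectorised over sites; per-site wrappers below)
# ---------------------------------------------------------------------------

def _site_partials_block(tipL, tipR, clL, clR, mode: NumericMode):
    """Vectorised PLF columns for all sites; clL/clR are (n, 4)."""
    dt = mode.dtype
    pl = tipL.astype(dt)
    pr = tipR.astype(dt)
    clL = clL.astype(dt)
    clR = clR.astype(dt)
    out = np.empty_like(clL)
    for s in range(N_STATES):
        # chained sum-of-products, in child-state order, one column at a time
        sopL = pl[s, 0] * clL[:, 0]
        sopR = pr[s, 0] * clR[:, 0]
        for x in range(1, N_STATES):
            sopL = sopL + pl[s, x] * clL[:, x]
            sopR = sopR + pr[s, x] * clR[:, x]
        out[:, s] = sopL * sopR
    return out


def compute_site_partials(tipL: TransitionMatrix, tipR: TransitionMatrix,
                          clL_site, clR_site,
                          mode: NumericMode = NumericMode.EXACT) -> np.ndarray:
    """One site's unscaled parent column clP[s] from the two children."""
    clL = np.asarray(clL_site, dtype=np.float64).reshape(1, N_STATES)
    clR = np.asarray(clR_site, dtype=np.float64).reshape(1, N_STATES)
    if not (np.all(np.isfinite(clL)) and np.all(np.isfinite(clR))):
        raise ValidationError("child partials must be finite")
    if np.any(clL < 0) or np.any(clR < 0):
        raise ValidationError("child partials must be non-negative")
    return _site_partials_block(tipL.p, tipR.p, clL, clR, mode)[0]


def _max_chain(block):
    """Max of the four columns via 3 compare/select pairs (ties keep the
    earlier state), matching the hardware comparison chain."""
    m = block[:, 0]
    for s in range(1, N_STATES):
        c = block[:, s]
        m = np.where(m >= c, m, c)
    return m


def rescale_site(clP_site):
    """Normalise one column by its maximum; returns (normalised, scaler)."""
    col = np.asarray(clP_site)
    m = _max_chain(col.reshape(1, N_STATES))[0]
    if not m > 0:
        raise DegenerateSiteError("all-zero likelihood column (numerical underflow)")
    return col / m, m


def update_partials_node(tipL: TransitionMatrix, tipR: TransitionMatrix,
                         clL: PartialsTable, clR: PartialsTable,
                         scale: ScaleBuffers,
                         mode: NumericMode = NumericMode.EXACT,
                         log_table: LogApproxTable | None = None) -> PartialsTable:
    """Full per-node update: PLF, max-rescale, scP and lnScaler bookkeeping.

    ``scale.scP`` is overwritten with this node's log-scalers and
    ``scale.lnScaler`` is accumulated additively (the cumulative buffer
    convention: it starts at zero and ends as the sum of log-scalers over
    every node processed).
    """
    if clL.n_sites != clR.n_sites:
        raise ValidationError("children are not site-aligned")
    clP = _site_partials_block(tipL.p, tipR.p, clL.values, clR.values, mode)
    scaler = _max_chain(clP)
    bad = ~(scaler > 0)
    if np.any(bad):
        k = int(np.argmax(bad))
        raise DegenerateSiteError(f"all-zero likelihood column at site {k}")
    norm = clP / scaler[:, None]
    scP = _ln(scaler, mode, log_table).astype(mode.dtype)
    scale.scP = scP
    scale.lnScaler = (scale.lnScaler.astype(mode.dtype) + scP)
    return PartialsTable(values=norm, role="internal")


def root_log_likelihood(root: PartialsTable, pi: StateFrequencies,
                        scale: ScaleBuffers, w: PatternWeights,
                        mode: NumericMode = NumericMode.EXACT,
                        log_table: LogApproxTable | None = None) -> float:
    """Weighted tree log-likelihood from the (already rescaled) root table."""
    dt = mode.dtype
    clP = root.values.astype(dt)
    bs = pi.pi.astype(dt)
    cond = bs[0] * clP[:, 0]
    for s in range(1, N_STATES):
        cond = cond + bs[s] * clP[:, s]
    if np.any(~(cond > 0)):
        k = int(np.argmax(~(cond > 0)))
        raise DegenerateSiteError(f"non-positive root likelihood at site {k}")
    ln_cond = np.asarray(_ln(cond, mode, log_table), dtype=dt)
    site = scale.lnScaler.astype(dt) + ln_cond
    contrib = w.w.astype(dt) * site
    # strictly left-to-right accumulation in site order
    return float(np.add.accumulate(contrib)[-1]) if len(contrib) else 0.0


# ---------------------------------------------------------------------------
# plain-text round trip for partials and weights
# ---------------------------------------------------------------------------

def write_partials(table: PartialsTable, path, weights: PatternWeights | None = None):
    """One site per line, four likelihood values (and optionally the
    pattern weight as a fifth column), tab-separated."""
    with open(path, "w") as fh:
        fh.write(f"# partials role={table.role} n_sites={table.n_sites}\n")
        for k in range(table.n_sites):
            cols = [repr(float(v)) for v in table.values[k]]
            if weights is not None:
                cols.append(str(int(weights.w[k])))
            fh.write("\t".join(cols) + "\n")


def read_partials(path):
    """Inverse of :func:`write_partials`; returns (PartialsTable, weights
    or None)."""
    role = "internal"
    rows, wts = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("role="):
                        role = tok[5:]
                continue
            parts = line.split("\t")
            rows.append([float(v) for v in parts[:N_STATES]])
            if len(parts) > N_STATES:
                wts.append(int(parts[N_STATES]))
    table = PartialsTable(values=np.array(rows, dtype=np.float64), role=role)
    weights = PatternWeights(np.array(wts)) if wts else None
    return table, weights
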