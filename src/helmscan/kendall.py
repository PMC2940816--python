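"""Tie-aware Kendall rank correlation (tau-b) with normal and exact inference.

This is the statistical engine of the selection scan.  Environmental
variables are defined per country but compared against per-population allele
frequencies, so one margin always carries large blocks of tied values; the
tau-b tie correction and the tie-adjusted variance of S are therefore not
optional refinements here but the working core of the method.

Conventions
-----------
* tau-b = S / sqrt((n0 - n1)(n0 - n2)) with S = C - D, n0 = n(n-1)/2 and
  n1, n2 the tied-pair counts of the two margins.
* The variance of S under the null uses the standard tie-adjusted formula
  (Kendall's "Rank Correlation Methods"); see :func:`tau_pvalue_normal`.
* A constant margin makes tau undefined; such inputs yield a *degenerate*
  result (``tau = nan``, ``p = 1``) rather than raising, so genome scans can
  proceed past monomorphic SNPs.
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import special

__all__ = [
    "TauResult",
    "kendall_tau_b",
    "tau_pvalue_normal",
    "tau_pvalue_exact",
    "correlate",
]

EXACT_MAX_N = 9  # n! permutations enumerated; 9! = 362,880 is the ceiling


@dataclass(frozen=True)
class TauResult:
    """One Kendall tau-b computation with its tie bookkeeping.

    Attributes
    ----------
    n : sample size after any caller-side filtering.
    C, D : concordant / discordant pair counts.
    S : C - D.
    tie_blocks_x, tie_blocks_y : sorted tuples of tie-group sizes > 1.
    tau : tau-b in [-1, 1]; nan when degenerate.
    degenerate : True when either margin is constant (tau undefined).
    var_S, z, p : filled by :func:`tau_pvalue_normal` (None until then,
        except degenerate results which carry p = 1 immediately).
    """

    n: int
    C: int
    D: int
    S: int
    tie_blocks_x: tuple[int, ...]
    tie_blocks_y: tuple[int, ...]
    tau: float
    degenerate: bool = False
    var_S: float | None = None
    z: float | None = None
    p: float | None = field(default=None)


def _tie_blocks(v: np.ndarray) -> tuple[int, ...]:
    _, counts = np.unique(v, return_counts=True)
    return tuple(sorted(int(c) for c in counts if c > 1))


def _pair_counts(x: np.ndarray, y: np.ndarray) -> tuple[int, int]:
    """Concordant and discordant pair counts by direct enumeration.

    O(n^2) but n is a population count (tens), not a SNP count.
    """
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    prod = dx * dy
    iu = np.triu_indices(len(x), k=1)
    s = prod[iu]
    return int(np.sum(s > 0)), int(np.sum(s < 0))


def kendall_tau_b(x, y) -> TauResult:
    """Compute Kendall's tau-b between two equal-length vectors.

    Missing values are the caller's responsibility (filter pairwise first).
    A constant margin returns a degenerate result with ``tau = nan`` and
    ``p = 1`` rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError(f"need n >= 3 observations, got {n}")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values not allowed; filter pairwise first")

    C, D = _pair_counts(x, y)
    S = C - D
    tx = _tie_blocks(x)
    ty = _tie_blocks(y)
    n0 = n * (n - 1) // 2
    n1 = sum(t * (t - 1) // 2 for t in tx)
    n2 = sum(t * (t - 1) // 2 for t in ty)
    if n1 == n0 or n2 == n0:  # a constant margin
        return TauResult(n, C, D, S, tx, ty, float("nan"),
                         degenerate=True, p=1.0)
    tau = S / math.sqrt((n0 - n1) * (n0 - n2))
    return TauResult(n, C, D, S, tx, ty, tau)


def tau_pvalue_normal(r: TauResult, continuity: bool = False) -> TauResult:
    """Fill var_S, z and a two-sided normal-approximation p-value.

    var_S = (v0 - vt - vu)/18 + v1 + v2 with
      v0 = n(n-1)(2n+5),
      vt = sum t(t-1)(2t+5) over tie blocks of x (vu likewise for y),
      v1 = [sum t(t-1)][sum u(u-1)] / (2 n(n-1)),
      v2 = [sum t(t-1)(t-2)][sum u(u-1)(u-2)] / (9 n(n-1)(n-2)).

    The approximation is adequate for n > 10 even with heavy ties; callers
    with smaller n should prefer :func:`tau_pvalue_exact`.
    """
    if r.degenerate:
        return replace(r, var_S=0.0, z=0.0, p=1.0)
    n = r.n
    tx, ty = r.tie_blocks_x, r.tie_blocks_y
    v0 = n * (n - 1) * (2 * n + 5)
    vt = sum(t * (t - 1) * (2 * t + 5) for t in tx)
    vu = sum(u * (u - 1) * (2 * u + 5) for u in ty)
    sum_tx2 = sum(t * (t - 1) for t in tx)
    sum_ty2 = sum(u * (u - 1) for u in ty)
    sum_tx3 = sum(t * (t - 1) * (t - 2) for t in tx)
    sum_ty3 = sum(u * (u - 1) * (u - 2) for u in ty)
    var_S = (v0 - vt - vu) / 18.0 \
        + sum_tx2 * sum_ty2 / (2.0 * n * (n - 1)) \
        + sum_tx3 * sum_ty3 / (9.0 * n * (n - 1) * (n - 2))
    if var_S <= 0:
        return replace(r, var_S=var_S, z=0.0, p=1.0, degenerate=True)
    s = float(r.S)
    if continuity and s != 0:
        s -= math.copysign(1.0, s)
    z = s / math.sqrt(var_S)
    # two-sided normal tail; erfc keeps precision for large |z|
    p = min(1.0, float(special.erfc(abs(z) / math.sqrt(2.0))))
    p = max(p, 5e-324)
    return replace(r, var_S=var_S, z=z, p=p)


@functools.lru_cache(maxsize=None)
def _perm_array(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def tau_pvalue_exact(x, y, max_n: int = EXACT_MAX_N) -> float:
    """Exact two-sided permutation p-value for Kendall's tau-b.

    p = fraction of the n! permutations of y whose |tau-b| is >= the
    observed |tau-b|.  The tie structure of y is permutation-invariant, so
    the tau-b denominator is constant and the test reduces to |S|; S is
    evaluated for all permutations at once with pairwise sign matrices.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n > max_n:
        raise ValueError(
            f"n = {n} > {max_n}: enumeration infeasible, use the normal "
            "approximation (tau_pvalue_normal)")
    obs = kendall_tau_b(x, y)
    if obs.degenerate:
        return 1.0
    iu, ju = np.triu_indices(n, k=1)
    sx = np.sign(x[ju] - x[iu]).astype(np.int8)
    perms = _perm_array(n)
    yp = y[perms]  # (n!, n)
    sy = np.sign(yp[:, ju] - yp[:, iu]).astype(np.int8)
    S_all = (sy * sx[None, :]).sum(axis=1, dtype=np.int64)
    return float(np.mean(np.abs(S_all) >= abs(obs.S)))


def correlate(x, y, min_n_normal: int = 11) -> TauResult:
    """Tau-b plus a p-value, choosing normal vs exact inference by n.

    For n >= ``min_n_normal`` the tie-adjusted normal approximation is used
    (its stated validity region).  Below that a warning is emitted and the
    exact permutation p is substituted when enumerable (n <= 9); at n = 10
    the normal approximation is retained with the warning.
    """
    import warnings

    r = kendall_tau_b(x, y)
    if r.degenerate:
        return tau_pvalue_normal(r)
    if r.n >= min_n_normal:
        return tau_pvalue_normal(r)
    warnings.warn(
        f"n = {r.n} < {min_n_normal}: normal approximation unreliable; "
        + ("using exact permutation p" if r.n <= EXACT_MAX_N
           else "exact enumeration infeasible, normal p retained"),
        stacklevel=2)
    r = tau_pvalue_normal(r)
    if r.n <= EXACT_MAX_N:
        r = replace(r, p=tau_pvalue_exact(x, y))
    return r
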