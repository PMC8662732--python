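"""Partial Correlation and Information Theory (PCIT) edge significance.

For every trio of variables (x, y, z) the three first-order partial
correlations are computed,

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))

and the trio-local tolerance is the mean of the absolute partial-to-direct
ratios,

    eps = (|r_xy.z / r_xy| + |r_xz.y / r_xz| + |r_yz.x / r_yz|) / 3.

The trio rejects the edge (x, y) iff |r_xy| <= |eps r_xz| and
|r_xy| <= |eps r_yz|; an edge is significant iff no third node rejects it.
Trios with a near-zero direct correlation or a non-positive denominator
under the square root are skipped (an undefined tolerance cannot support a
rejection).

``pcit`` vectorises the scan over the third node z (O(n) passes of O(n^2)
work); ``pcit_bruteforce`` is the literal triple loop kept as an
independent reference for testing.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

ZERO_TOL = 1e-12
BRUTEFORCE_SIZE_BOUND = 200


def _validate_corr(corr) -> tuple[np.ndarray, list | None]:
    labels = None
    if isinstance(corr, pd.DataFrame):
        labels = list(corr.index)
        corr = corr.to_numpy()
    r = np.asarray(corr, dtype=float)
    if r.ndim != 2 or r.shape[0] != r.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(r, r.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if r.shape[0] < 3:
        raise ValueError("PCIT needs at least 3 variables")
    return r, labels


def pcit(corr) -> np.ndarray | pd.DataFrame:
    """Significant-edge mask for a correlation matrix.

    Returns a boolean matrix (same labels as the input if it was a
    DataFrame) with True where the edge survives every trio; the diagonal
    is False.
    """
    r, labels = _validate_corr(corr)
    n = r.shape[0]
    absr = np.abs(r)
    one_minus_sq = 1.0 - r * r
    reject = np.zeros((n, n), dtype=bool)
    idx = np.arange(n)

    with np.errstate(invalid="ignore", divide="ignore"):
        for z in range(n):
            a = r[:, z]  # r_xz for all x
            abs_a = np.abs(a)
            da = 1.0 - a * a
            denom_xy = da[:, None] * da[None, :]
            denom_xz = one_minus_sq * da[None, :]
            denom_yz = one_minus_sq * da[:, None]

            p_xy = (r - np.outer(a, a)) / np.sqrt(denom_xy)
            p_xz = (a[:, None] - r * a[None, :]) / np.sqrt(denom_xz)
            p_yz = (a[None, :] - r * a[:, None]) / np.sqrt(denom_yz)

            valid = (
                (absr > ZERO_TOL)
                & (abs_a[:, None] > ZERO_TOL)
                & (abs_a[None, :] > ZERO_TOL)
                & (denom_xy > 0)
                & (denom_xz > 0)
                & (denom_yz > 0)
            )
            tol = (
                np.abs(p_xy / r)
                + np.abs(p_xz / a[:, None])
                + np.abs(p_yz / a[None, :])
            ) / 3.0
            rej = (
                valid
                & (absr <= tol * abs_a[:, None])
                & (absr <= tol * abs_a[None, :])
            )
            rej[z, :] = False
            rej[:, z] = False
            rej[idx, idx] = False
            reject |= rej

    sig = (~reject) & (absr > ZERO_TOL)
    sig[idx, idx] = False
    if labels is not None:
        return pd.DataFrame(sig, index=labels, columns=labels)
    return sig


def _trio(r: np.ndarray, x: int, y: int, z: int):
    """Partials and tolerance of one trio; None when the trio is skipped."""
    rxy, rxz, ryz = r[x, y], r[x, z], r[y, z]
    if min(abs(rxy), abs(rxz), abs(ryz)) < ZERO_TOL:
        return None
    d_xy = (1.0 - rxz**2) * (1.0 - ryz**2)
    d_xz = (1.0 - rxy**2) * (1.0 - ryz**2)
    d_yz = (1.0 - rxy**2) * (1.0 - rxz**2)
    if d_xy <= 0 or d_xz <= 0 or d_yz <= 0:
        return None
    p_xy = (rxy - rxz * ryz) / np.sqrt(d_xy)
    p_xz = (rxz - rxy * ryz) / np.sqrt(d_xz)
    p_yz = (ryz - rxy * rxz) / np.sqrt(d_yz)
    eps = (abs(p_xy / rxy) + abs(p_xz / rxz) + abs(p_yz / ryz)) / 3.0
    return p_xy, p_xz, p_yz, eps


def pcit_bruteforce(corr) -> np.ndarray | pd.DataFrame:
    """Literal O(n^3) triple-loop PCIT; reference oracle for n <= 200."""
    r, labels = _validate_corr(corr)
    n = r.shape[0]
    if n > BRUTEFORCE_SIZE_BOUND:
        warnings.warn(
            f"pcit_bruteforce on n={n} > {BRUTEFORCE_SIZE_BOUND}; this is slow",
            stacklevel=2,
        )
    sig = np.zeros((n, n), dtype=bool)
    for x in range(n):
        for y in range(x + 1, n):
            if abs(r[x, y]) <= ZERO_TOL:
                continue
            significant = True
            for z in range(n):
                if z == x or z == y:
                    continue
                trio = _trio(r, x, y, z)
                if trio is None:
                    continue
                eps = trio[3]
                if abs(r[x, y]) <= abs(eps * r[x, z]) and abs(r[x, y]) <= abs(
                    eps * r[y, z]
                ):
                    significant = False
                    break
            sig[x, y] = sig[y, x] = significant
    if labels is not None:
        return pd.DataFrame(sig, index=labels, columns=labels)
    return sig


def trio_partials(rxy: float, rxz: float, ryz: float):
    """First-order partials and tolerance for a single trio of direct
    correlations; convenience for inspection and testing."""
    r = np.array([[1.0, rxy, rxz], [rxy, 1.0, ryz], [rxz, ryz, 1.0]])
    out = _trio(r, 0, 1, 2)
    if out is None:
        raise ValueError("degenerate trio")
    return out
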