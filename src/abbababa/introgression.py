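"""Correction for gene flow from an external population and admixture-rate
estimation.

When an external population H5 has contributed a fraction ``alpha`` of the
genome of one ingroup (H1 or H2), every observed four-allele pattern
probability of the tested tree T1:4 = (((H1,H2)H3)H4) is a mixture

    p_1:4 = (1 - alpha) * p_un + alpha * p_out

where p_out comes from the tree with H5 substituted for the admixed
population and p_un is the pattern probability of the unadmixed tree.
Solving gives p_un = (p_1:4 - alpha * p_out) / (1 - alpha); computing the
D-statistic from p_un removes the effect of the pulse.  If alpha is
unknown it can be estimated as the value at which the corrected statistic
D_un crosses zero, since the unadmixed tree satisfies the null.

D_un(alpha) is a ratio of affine functions of alpha, hence continuous and
monotone between its poles, so bisection finds the root.  Corrections here
stay linear (no clamping of negative pattern mass) so that E[D_un] = 0 at
the true alpha is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dstat import jackknife_D, pattern_masses
from .error import apply_negativity_policy


@dataclass
class AlphaEstimate:
    """Admixture proportion at which the corrected D-statistic vanishes."""

    alpha_hat: float
    SE: float
    grid: np.ndarray  # alpha values scanned
    curve: np.ndarray  # D_un(alpha) on the grid
    converged: bool


class NoRootError(RuntimeError):
    """D_un does not change sign on [0, alpha_max]; carries the grid curve."""

    def __init__(self, grid, curve):
        super().__init__("D_un(alpha) has no sign change on the search interval")
        self.grid = np.asarray(grid)
        self.curve = np.asarray(curve)


def correct_admixture(p_1to4, p_out, alpha: float, policy: str = "raw"):
    """Remove an admixture pulse of proportion ``alpha`` from pattern mass.

    Entrywise affine combination (p_1to4 - alpha * p_out) / (1 - alpha);
    inputs may be 256-vectors, pattern tensors or stacks thereof.  At
    ``alpha = 0`` the input is returned unchanged.  ``policy="clamp"``
    zeroes negative entries and rescales (per leading entry); the default
    propagates raw values, keeping the correction linear.
    """
    if not (0.0 <= alpha < 1.0):
        raise ValueError("admixture proportion must lie in [0, 1)")
    p14 = np.asarray(p_1to4, dtype=float)
    pout = np.asarray(p_out, dtype=float)
    if p14.shape != pout.shape:
        raise ValueError("pattern arrays for T1:4 and Tout must share a shape")
    out = (p14 - alpha * pout) / (1.0 - alpha)
    if policy != "raw":
        lead = out.reshape(-1, out.shape[-1]) if out.ndim > 1 else out[None]
        rows = [apply_negativity_policy(r, policy)[0] for r in lead]
        out = np.stack(rows).reshape(out.shape)
    return out


def _masses(tensors, transversions_only):
    abba, baba = pattern_masses(tensors, transversions_only=transversions_only)
    return baba - abba, baba + abba  # X_b, Y_b


def _d_un(alpha, X14, Y14, Xout, Yout):
    num = (X14.sum() - alpha * Xout.sum())
    den = (Y14.sum() - alpha * Yout.sum())
    return num / den


def estimate_alpha(
    blocks_1to4: np.ndarray,
    blocks_out: np.ndarray,
    alpha_max: float = 0.5,
    tol: float = 1e-4,
    transversions_only: bool = False,
    grid_points: int = 51,
) -> AlphaEstimate:
    """Estimate the admixture proportion by root-finding on D_un(alpha).

    Parameters
    ----------
    blocks_1to4, blocks_out
        Per-block pattern-mass tensors (B, 4,4,4,4) (or (B, 256)) for the
        tested tree and for the tree with the source population substituted
        for the admixed ingroup.
    alpha_max
        Upper search bound; beyond 0.5 the "minor contributor" reading of
        alpha inverts.
    tol
        Bisection tolerance on alpha.

    The standard error is a delete-one-block jackknife: the root is
    re-estimated on every leave-one-block-out dataset.

    Raises
    ------
    NoRootError
        If D_un does not change sign on [0, alpha_max]; the exception
        carries the grid curve for inspection.
    """
    b14 = np.asarray(blocks_1to4, dtype=float)
    bout = np.asarray(blocks_out, dtype=float)
    if b14.shape != bout.shape:
        raise ValueError("block arrays must share a shape")
    if b14.ndim == 2 and b14.shape[-1] == 256:
        b14 = b14.reshape(-1, 4, 4, 4, 4)
        bout = bout.reshape(-1, 4, 4, 4, 4)
    X14, Y14 = _masses(b14, transversions_only)
    Xout, Yout = _masses(bout, transversions_only)

    grid = np.linspace(0.0, alpha_max, grid_points)
    curve = np.array([_d_un(a, X14, Y14, Xout, Yout) for a in grid])

    def bisect_root(X14_, Y14_, Xout_, Yout_):
        # D_un is a ratio of affine functions of alpha; its zero is the
        # zero of the numerator, so bisect on that (the denominator can
        # have a pole inside the interval without affecting the root)
        def num(a):
            return X14_.sum() - a * Xout_.sum()

        lo, hi = 0.0, alpha_max
        f_lo, f_hi = num(lo), num(hi)
        if f_lo == 0.0:
            return lo
        if np.sign(f_lo) == np.sign(f_hi):
            return None
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            f_mid = num(mid)
            if f_mid == 0.0:
                return mid
            if np.sign(f_mid) == np.sign(f_lo):
                lo, f_lo = mid, f_mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    root = bisect_root(X14, Y14, Xout, Yout)
    if root is None:
        raise NoRootError(grid, curve)

    g = len(X14)
    loo = []
    for b in range(g):
        keep = np.arange(g) != b
        r = bisect_root(X14[keep], Y14[keep], Xout[keep], Yout[keep])
        if r is not None:
            loo.append(r)
    if len(loo) >= 2:
        loo = np.asarray(loo)
        k = len(loo)
        var = (k - 1) / k * ((loo - loo.mean()) ** 2).sum()
        se = float(np.sqrt(var))
    else:
        se = float("nan")
    return AlphaEstimate(alpha_hat=float(root), SE=se, grid=grid, curve=curve,
                         converged=True)


def corrected_D(blocks_1to4, blocks_out, alpha: float,
                transversions_only: bool = False, site_counts=None):
    """Jackknifed D-statistic after removing a pulse of known ``alpha``."""
    b14 = np.asarray(blocks_1to4, dtype=float)
    bout = np.asarray(blocks_out, dtype=float)
    corrected = correct_admixture(b14, bout, alpha)
    abba, baba = pattern_masses(corrected, transversions_only=transversions_only)
    blocks = ((baba - abba, baba + abba) if site_counts is None
              else (baba - abba, baba + abba, site_counts))
    res = jackknife_D(blocks)
    res.corrections = {"admixture_alpha": float(alpha)}
    return res
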