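"""Type-specific sequencing-error estimation and correction.

A type-specific error matrix is a row-stochastic 4x4 matrix ``e`` with
``e[a, b]`` the probability of reading base ``b`` when the true base is
``a``.  Ancient-DNA deamination typically inflates specific transitions
(for instance C->T), which biases ABBA/BABA pattern counts.

Estimation uses a trio ((T, R), O): an error-affected individual T, an
error-free individual R and an outgroup O.  Conditional on the outgroup
base, T and R share the same distribution of true bases, so the observed
conditional base distributions satisfy ``P_T = P_R @ e`` and ``e`` can be
recovered by least squares constrained to the row-stochastic simplex.

Correction applies the inverse channel, either per individual on a 4-vector
of base frequencies, or at the group level on the 256-vector of joint
four-population allele patterns, where the group operator factorises as a
tensor product of the four per-population mean matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize

from .data_model import BASES, ParseError


class EstimationError(RuntimeError):
    """Error-matrix estimation failed (ill-conditioned or empty data)."""


@dataclass(frozen=True)
class ErrorMatrix:
    """Row-stochastic 4x4 matrix of base-miscall probabilities."""

    e: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.e, dtype=float)
        if e.shape != (4, 4):
            raise ValueError("error matrix must be 4x4")
        if (e < -1e-12).any() or (e > 1 + 1e-12).any():
            raise ValueError("error-matrix entries must lie in [0, 1]")
        if not np.allclose(e.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("error-matrix rows must sum to 1")
        off = e - np.diag(np.diag(e))
        if (off > 0.5).any():
            warnings.warn("error matrix has an off-diagonal entry > 0.5")
        object.__setattr__(self, "e", np.clip(e, 0.0, 1.0))

    @classmethod
    def identity(cls) -> "ErrorMatrix":
        return cls(np.eye(4))

    @classmethod
    def single_error(cls, src: str, dst: str, rate: float) -> "ErrorMatrix":
        """Matrix with one type-specific miscall, e.g. A->G at 0.005."""
        e = np.eye(4)
        i, j = BASES.index(src), BASES.index(dst)
        e[i, i] -= rate
        e[i, j] += rate
        return cls(e)

    def __matmul__(self, other):
        return self.e @ (other.e if isinstance(other, ErrorMatrix) else other)

    def forward(self, p_true: np.ndarray) -> np.ndarray:
        """Distribution of observed bases for true base frequencies ``p_true``."""
        return np.asarray(p_true) @ self.e

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("true\\obs\t" + "\t".join(BASES) + "\n")
            for i, b in enumerate(BASES):
                fh.write(b + "\t" + "\t".join(f"{x:.8g}" for x in self.e[i]) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "ErrorMatrix":
        rows = []
        with open(path) as fh:
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                if not fields or fields[0].startswith("true"):
                    continue
                if len(fields) != 5 or fields[0] not in BASES:
                    raise ParseError(f"malformed error-matrix row: {line!r}")
                rows.append([float(x) for x in fields[1:]])
        if len(rows) != 4:
            raise ParseError("error-matrix file must contain 4 base rows")
        return cls(np.array(rows))


def apply_negativity_policy(vec: np.ndarray, policy: str = "clamp"):
    """Handle negative entries produced by inverse-channel correction.

    ``clamp``: zero out negatives and rescale to the pre-clamp total (a
    warning reports the clamped mass); ``raw``: propagate values unchanged.
    Returns ``(vector, clamped_mass)``.
    """
    vec = np.asarray(vec, dtype=float)
    neg = vec < 0
    clamped = float(-vec[neg].sum())
    if policy == "raw" or not neg.any():
        return vec, 0.0 if policy != "raw" else clamped
    if policy != "clamp":
        raise ValueError(f"unknown negativity policy {policy!r}")
    total = vec.sum()
    out = np.where(neg, 0.0, vec)
    s = out.sum()
    if s > 0 and total > 0:
        out = out * (total / s)
    return out, clamped


def estimate_error_matrix(counts_T_vs_O, counts_R_vs_O) -> ErrorMatrix:
    """Estimate a type-specific error matrix from trio count tables.

    Both arguments are 4x4 integer tables with rows indexed by the outgroup
    base and columns by the individual's observed base: ``counts_T_vs_O``
    tallies the reads of the error-affected individual, ``counts_R_vs_O``
    those (or consensus calls) of the error-free individual.  Outgroup
    bases with no data are excluded from the fit with a warning.
    """
    cT = np.asarray(counts_T_vs_O, dtype=float)
    cR = np.asarray(counts_R_vs_O, dtype=float)
    if cT.shape != (4, 4) or cR.shape != (4, 4):
        raise ValueError("trio count tables must be 4x4")
    rows = (cT.sum(axis=1) >= 1) & (cR.sum(axis=1) >= 1)
    if not rows.any():
        raise EstimationError("no outgroup base has data in both individuals")
    if not rows.all():
        warnings.warn(
            f"outgroup bases {[BASES[i] for i in np.where(~rows)[0]]} have no data; excluded"
        )
    P_T = cT[rows] / cT[rows].sum(axis=1, keepdims=True)
    P_R = cR[rows] / cR[rows].sum(axis=1, keepdims=True)
    if rows.sum() == 4 and np.linalg.cond(P_R) > 1e8:
        raise EstimationError(
            "conditional base distribution of the error-free individual is "
            "ill-conditioned; more sites (or more divergent outgroup rows) needed"
        )

    # least squares on the row-stochastic simplex, started from the
    # unconstrained solution projected onto the feasible set
    x0 = np.linalg.lstsq(P_R, P_T, rcond=None)[0] if rows.sum() == 4 else np.eye(4)
    x0 = np.clip(x0, 0.0, 1.0)
    x0 /= np.maximum(x0.sum(axis=1, keepdims=True), 1e-12)

    def objective(x):
        E = x.reshape(4, 4)
        r = P_R @ E - P_T
        return float((r * r).sum())

    def jac(x):
        E = x.reshape(4, 4)
        return (2.0 * P_R.T @ (P_R @ E - P_T)).ravel()

    constraints = [
        {"type": "eq",
         "fun": (lambda x, i=i: x.reshape(4, 4)[i].sum() - 1.0),
         "jac": (lambda x, i=i: np.kron(np.eye(4)[i], np.ones(4)))}
        for i in range(4)
    ]
    res = minimize(objective, x0.ravel(), jac=jac, method="SLSQP",
                   bounds=[(0.0, 1.0)] * 16, constraints=constraints,
                   options={"maxiter": 400, "ftol": 1e-14})
    if not res.success and objective(res.x) > objective(x0.ravel()):
        res.x = x0.ravel()
    e = res.x.reshape(4, 4)
    e = np.clip(e, 0.0, 1.0)
    e /= e.sum(axis=1, keepdims=True)
    return ErrorMatrix(e)


def correct_individual_freqs(p_observed, e: ErrorMatrix, policy: str = "clamp"):
    """Invert the error channel on one individual's base-frequency 4-vector.

    For true frequencies ``p_G`` the observed frequencies are
    ``p_T = p_G @ e``; this returns ``p_T @ e^{-1}``.  Negative entries
    (possible when the channel is strong) are handled by ``policy``.
    """
    p = np.asarray(p_observed, dtype=float)
    cond = np.linalg.cond(e.e)
    if not np.isfinite(cond) or cond > 1e10:
        raise np.linalg.LinAlgError("error matrix is not invertible")
    corrected = np.linalg.solve(e.e.T, p)
    out, clamped = apply_negativity_policy(corrected, policy)
    if clamped > 0 and policy == "clamp":
        warnings.warn(f"clamped negative frequency mass {clamped:.3g} after correction")
    return out


def mean_population_error(matrices: Iterable[ErrorMatrix]) -> ErrorMatrix:
    """Entrywise mean of per-individual error matrices (one population)."""
    mats = [m.e if isinstance(m, ErrorMatrix) else np.asarray(m, float) for m in matrices]
    if not mats:
        raise ValueError("need at least one error matrix")
    return ErrorMatrix(np.mean(mats, axis=0))


@dataclass(frozen=True)
class GroupErrorOperator:
    """Tensor-product error channel on 256 four-population allele patterns.

    ``E[(a1..a4), (b1..b4)] = e1[a1,b1] e2[a2,b2] e3[a3,b3] e4[a4,b4]``.
    The operator is applied through its 4x4 factors; the dense 256x256
    matrix is only materialised on request.  The inverse channel is the
    tensor product of the factor inverses.
    """

    factors: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]

    @classmethod
    def from_matrices(cls, e1, e2, e3, e4) -> "GroupErrorOperator":
        mats = []
        for m in (e1, e2, e3, e4):
            a = m.e if isinstance(m, ErrorMatrix) else np.asarray(m, dtype=float)
            cond = np.linalg.cond(a)
            if not np.isfinite(cond) or cond > 1e10:
                raise np.linalg.LinAlgError("a factor error matrix is not invertible")
            mats.append(a)
        return cls(tuple(mats))

    def _apply(self, tensor: np.ndarray, mats: Sequence[np.ndarray]) -> np.ndarray:
        t = np.asarray(tensor, dtype=float)
        shape = t.shape
        t = t.reshape(-1, 4, 4, 4, 4)
        out = np.einsum("sabcd,ax,by,cz,dw->sxyzw", t, *mats, optimize=True)
        return out.reshape(shape)

    def apply(self, tensor: np.ndarray) -> np.ndarray:
        """Forward channel: pattern tensor of true alleles -> observed."""
        return self._apply(tensor, self.factors)

    def apply_inverse(self, tensor: np.ndarray) -> np.ndarray:
        """Inverse channel: observed pattern tensor -> error-corrected."""
        return self._apply(tensor, [np.linalg.inv(m) for m in self.factors])

    def dense(self) -> np.ndarray:
        """Dense 256x256 matrix, pattern index = 64*a1 + 16*a2 + 4*a3 + a4."""
        m = self.factors
        return np.kron(m[0], np.kron(m[1], np.kron(m[2], m[3])))


def build_group_error_matrix(e1, e2, e3, e4) -> GroupErrorOperator:
    """Group-level 256-pattern error operator from four 4x4 matrices."""
    return GroupErrorOperator.from_matrices(e1, e2, e3, e4)


def correct_pattern_probs(p_error: np.ndarray, operator: GroupErrorOperator,
                          policy: str = "clamp") -> np.ndarray:
    """Error-correct a 256-pattern probability (or mass) vector.

    Accepts a flat 256-vector or a (..., 4, 4, 4, 4) tensor; leading axes
    (e.g. genomic blocks) are corrected independently.  The default policy
    clamps negative corrected entries and rescales; pass ``policy="raw"``
    to propagate them, which keeps the correction linear and therefore
    unbiased for downstream sums.
    """
    p = np.asarray(p_error, dtype=float)
    flat = p.ndim == 1 or p.shape[-1] == 256
    t = p.reshape(p.shape[:-1] + (4, 4, 4, 4)) if flat else p
    corr = operator.apply_inverse(t)
    if policy != "raw":
        lead = corr.reshape(-1, 256)
        rows = []
        clamped_total = 0.0
        for row in lead:
            out, clamped = apply_negativity_policy(row, policy)
            clamped_total += clamped
            rows.append(out)
        corr = np.stack(rows).reshape(corr.shape)
        if clamped_total > 0:
            warnings.warn(f"clamped negative pattern mass {clamped_total:.3g}")
    return corr.reshape(p.shape)
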