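"""Weighted single-random-effect mixed model: REML and Henderson's MME.

The model is the genomic-prediction working model

    y = 1*mu + Z*g + e,    g ~ N(0, K*sigma2_g),   e ~ N(0, D*sigma2_e),

where ``y`` holds de-regressed proofs (DRP) of the reference animals,
``K`` is any relationship matrix (G for GBLUP, H or adjusted-H for
one-step blending), ``Z`` maps records to animals, and ``D`` is diagonal
with ``d_ii = 1/w_i``, ``w_i = r2_i / (1 - r2_i)`` for DRP reliability
``r2_i`` — a highly reliable proof behaves like many repeated records.

Variance components are estimated by restricted maximum likelihood,
parameterized through the ratio ``lambda = sigma2_e / sigma2_g``: the
profile REML log-likelihood is maximized over ``log lambda`` by bounded
1-D search, optionally followed by a 2-D simplex polish of
``(log sigma2_g, log sigma2_e)``.

Predictions, prediction-error variances (PEV) and theoretical accuracies
come from the mixed-model equations; with ``W = D^-1``,

    [ 1'W1   1'WZ          ] [mu]   [1'Wy]
    [ Z'W1   Z'WZ + K^-1*L ] [g ] = [Z'Wy],    L = lambda,

whose inverse, scaled by sigma2_e, yields PEV_i on the g-block diagonal
and ``theoretical accuracy = sqrt(1 - PEV_i / (K_ii * sigma2_g))``.
Animals present in K but without records (validation animals) receive
predictions and accuracies purely through K.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from .relmat import RelationshipMatrix, StructuralError

__all__ = [
    "MixedModelSpec",
    "VarianceComponents",
    "MMEFit",
    "build_weights",
    "reml_fit",
    "solve_mme",
    "theoretical_accuracy",
]

logger = logging.getLogger(__name__)

_JITTER_LADDER = (0.0, 1e-8, 1e-6, 1e-4)
_LOG_LAMBDA_BOUNDS = (-12.0, 12.0)


def build_weights(rel_drp: np.ndarray) -> np.ndarray:
    """Record weights w = r2/(1-r2); the residual covariance is D*sigma2_e
    with d_ii = 1/w_i."""
    r = np.asarray(rel_drp, dtype=float)
    if np.any((r <= 0.0) | (r >= 1.0)):
        raise ValueError("DRP reliabilities must lie strictly in (0, 1)")
    return r / (1.0 - r)


@dataclass
class MixedModelSpec:
    """One trait's records mapped onto a relationship matrix."""

    y: np.ndarray
    weights: np.ndarray
    K: RelationshipMatrix
    record_animal_ids: list[str]
    kind_label: str = "GBLUP"  # GBLUP | one_step | adjusted_one_step

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.y)
        if len(self.weights) != n or len(self.record_animal_ids) != n:
            raise ValueError("y, weights and record_animal_ids must have equal length")
        if np.any(self.weights <= 0.0):
            raise ValueError("weights must be strictly positive")
        self._ridx = self.K.index_of(self.record_animal_ids)

    @property
    def n_records(self) -> int:
        return len(self.y)

    def record_K(self) -> np.ndarray:
        """ZKZ' — the relationship matrix between records."""
        return self.K.values[np.ix_(self._ridx, self._ridx)]


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float
    converged: bool
    loglik: float
    n_evals: int = 0

    @property
    def lam(self) -> float:
        return self.sigma2_e / self.sigma2_g


@dataclass
class MMEFit:
    """Solved mixed model: predictions with their error variances."""

    animal_ids: list[str]
    mu_hat: float
    g_hat: np.ndarray
    pev: np.ndarray
    theo_acc: np.ndarray
    vc: VarianceComponents
    kind_label: str
    jitter: float = 0.0
    _cgg_diag: np.ndarray | None = field(default=None, repr=False)

    def g_hat_for(self, ids: list[str]) -> np.ndarray:
        pos = {a: i for i, a in enumerate(self.animal_ids)}
        return self.g_hat[[pos[a] for a in ids]]

    def theo_acc_for(self, ids: list[str]) -> np.ndarray:
        pos = {a: i for i, a in enumerate(self.animal_ids)}
        return self.theo_acc[[pos[a] for a in ids]]


def _reml_pieces(V: np.ndarray, y: np.ndarray):
    """Cholesky-based REML ingredients for a given record covariance V."""
    cho = linalg.cho_factor(V, lower=True)
    logdet_V = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    ones = np.ones_like(y)
    Vi1 = linalg.cho_solve(cho, ones)
    Viy = linalg.cho_solve(cho, y)
    xvx = float(ones @ Vi1)
    Py = Viy - Vi1 * (float(ones @ Viy) / xvx)
    yPy = float(y @ Py)
    return logdet_V, xvx, yPy


def _profile_negloglik(log_lam: float, Krr: np.ndarray, d: np.ndarray, y: np.ndarray) -> float:
    n = len(y)
    lam = np.exp(log_lam)
    try:
        logdet_V, xvx, yPy = _reml_pieces(Krr + lam * np.diag(d), y)
    except linalg.LinAlgError:
        return np.inf
    if yPy <= 0.0 or xvx <= 0.0:
        return np.inf
    sigma2_g = yPy / (n - 1)
    ll = -0.5 * ((n - 1) * (np.log(sigma2_g) + 1.0) + logdet_V + np.log(xvx))
    return -ll


def _full_negloglik(theta: np.ndarray, Krr: np.ndarray, d: np.ndarray, y: np.ndarray) -> float:
    sg2, se2 = np.exp(theta)
    try:
        logdet_V, xvx, yPy = _reml_pieces(Krr * sg2 + np.diag(d) * se2, y)
    except linalg.LinAlgError:
        return np.inf
    if xvx <= 0.0:
        return np.inf
    return 0.5 * (logdet_V + np.log(xvx) + yPy)


def reml_fit(spec: MixedModelSpec, polish: bool = True, tol: float = 1e-10) -> VarianceComponents:
    """Estimate (sigma2_g, sigma2_e) by profile REML on lambda.

    ``converged`` is True only for an interior optimum of the lambda search
    (an estimate pinned at the search boundary — e.g. y essentially constant
    driving sigma2_g to 0 — is returned with converged=False rather than
    raising).
    """
    if spec.n_records < 10:
        raise ValueError("REML needs at least 10 records")
    Krr = spec.record_K()
    d = 1.0 / spec.weights
    y = spec.y
    n = spec.n_records

    res = optimize.minimize_scalar(
        _profile_negloglik,
        bounds=_LOG_LAMBDA_BOUNDS,
        args=(Krr, d, y),
        method="bounded",
        options={"xatol": 1e-9},
    )
    n_evals = int(res.nfev)
    log_lam = float(res.x)
    lo, hi = _LOG_LAMBDA_BOUNDS
    interior = (log_lam - lo > 1e-3) and (hi - log_lam > 1e-3)
    if not np.isfinite(res.fun):
        return VarianceComponents(np.nan, np.nan, False, -np.inf, n_evals)

    lam = np.exp(log_lam)
    logdet_V, xvx, yPy = _reml_pieces(Krr + lam * np.diag(d), y)
    sigma2_g = yPy / (n - 1)
    sigma2_e = lam * sigma2_g
    # report the log-likelihood on one fixed scale (constants dropped)
    loglik = -_full_negloglik(np.log([sigma2_g, sigma2_e]), Krr, d, y)

    if polish and interior:
        theta0 = np.log([sigma2_g, sigma2_e])
        pol = optimize.minimize(
            _full_negloglik,
            theta0,
            args=(Krr, d, y),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": tol, "maxiter": 200},
        )
        n_evals += int(pol.nfev)
        # accept the polish only if it does not degrade the (unprofiled)
        # objective at the start point
        if np.isfinite(pol.fun) and pol.fun <= _full_negloglik(theta0, Krr, d, y):
            sigma2_g, sigma2_e = np.exp(pol.x)
            loglik = -float(pol.fun)

    converged = bool(interior and sigma2_g > 0 and sigma2_e > 0)
    if not converged:
        logger.warning(
            "REML did not converge to an interior optimum (log lambda = %.3f)", log_lam
        )
    return VarianceComponents(float(sigma2_g), float(sigma2_e), converged, float(loglik), n_evals)


def _factor_K_inverse(K: np.ndarray) -> tuple[np.ndarray, float]:
    """K^-1 by symmetric factorization with a jitter ladder on the diagonal.

    A genomic K centered with sample allele frequencies is exactly singular
    (K @ 1 = 0), yet floating-point Cholesky can still "succeed" on it and
    return a meaningless inverse.  The factor's diagonal decay is therefore
    checked: an effective condition worse than ~1e12 escalates the ladder.
    """
    for jitter in _JITTER_LADDER:
        try:
            cho = linalg.cho_factor(K + jitter * np.eye(len(K)), lower=True)
        except linalg.LinAlgError:
            continue
        d = np.diag(cho[0])
        if (d.min() / d.max()) ** 2 < 1e-12:
            continue  # numerically rank deficient: escalate jitter
        if jitter:
            logger.info("K factorization required diagonal jitter %.1e", jitter)
        return linalg.cho_solve(cho, np.eye(len(K))), jitter
    raise StructuralError(
        "relationship matrix K is not positive definite even with jitter "
        f"(condition number {np.linalg.cond(K):.3e})"
    )


def solve_mme(spec: MixedModelSpec, vc: VarianceComponents) -> MMEFit:
    """Assemble and solve the mixed-model equations; returns predictions,
    PEV and theoretical accuracy for every animal in K."""
    if not (vc.sigma2_g > 0 and vc.sigma2_e > 0):
        raise ValueError("variance components must be strictly positive")
    K = spec.K.values
    q = len(K)
    lam = vc.lam
    w = spec.weights
    y = spec.y
    ridx = spec._ridx

    Kinv, jitter = _factor_K_inverse(K)

    # sigma2_e-scaled coefficient matrix: [[1'W1, 1'WZ], [Z'W1, Z'WZ + Kinv*lam]]
    C = np.zeros((q + 1, q + 1))
    zw = np.zeros(q)
    np.add.at(zw, ridx, w)
    zwy = np.zeros(q)
    np.add.at(zwy, ridx, w * y)
    C[0, 0] = w.sum()
    C[0, 1:] = zw
    C[1:, 0] = zw
    C[1:, 1:] = Kinv * lam
    C[np.arange(1, q + 1), np.arange(1, q + 1)] += zw
    rhs = np.concatenate(([w @ y], zwy))

    try:
        cho = linalg.cho_factor(C, lower=True)
    except linalg.LinAlgError as e:
        raise StructuralError(
            "MME coefficient matrix is singular; "
            f"g-block (Z'WZ + K^-1*lambda) condition number {np.linalg.cond(C[1:, 1:]):.3e}"
        ) from e
    sol = linalg.cho_solve(cho, rhs)
    Cinv = linalg.cho_solve(cho, np.eye(q + 1))
    cgg_diag = np.diag(Cinv)[1:]

    mu_hat = float(sol[0])
    g_hat = sol[1:]
    pev, acc = theoretical_accuracy(cgg_diag, spec.K, vc)
    return MMEFit(
        animal_ids=list(spec.K.animal_ids),
        mu_hat=mu_hat,
        g_hat=g_hat,
        pev=pev,
        theo_acc=acc,
        vc=vc,
        kind_label=spec.kind_label,
        jitter=jitter,
        _cgg_diag=cgg_diag,
    )


def theoretical_accuracy(
    cgg_diag: np.ndarray, K: RelationshipMatrix, vc: VarianceComponents
) -> tuple[np.ndarray, np.ndarray]:
    """PEV and per-animal theoretical accuracy from the inverse MME.

    ``cgg_diag`` is the diagonal of the g-block of the inverse of the
    sigma2_e-scaled coefficient matrix, so PEV_i = cgg_diag_i * sigma2_e and
    accuracy_i = sqrt(1 - PEV_i / (K_ii * sigma2_g)), clamped to [0, 1].
    """
    kdiag = np.diag(K.values)
    if np.any(kdiag <= 0.0):
        raise ValueError("K has non-positive diagonal entries")
    pev = np.asarray(cgg_diag, dtype=float) * vc.sigma2_e
    rel = 1.0 - pev / (kdiag * vc.sigma2_g)
    acc = np.sqrt(np.clip(rel, 0.0, 1.0))
    return pev, acc
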