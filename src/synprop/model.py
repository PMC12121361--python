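"""Graph-propagational risk model.

The model converts per-protein expression values ("independent effects",
X in R^{d x n}) into interaction-aware representations ("synergetic
effects", Z) by minimizing, per participant column z with data column x,

    sum_{i~j} W_ij (z_i - z_j)^2  +  sum_i phi_i (z_i - x_i)^2,

a smoothness term over the weighted PPI graph plus a per-protein
steadiness term whose intensity phi_i > 0 controls how strongly protein i
holds on to its own expression.  With the symmetric normalized Laplacian
L = I - D^{-1/2} W D^{-1/2} the minimizer is the closed-form linear solve

    Z = (Phi + L)^{-1} Phi X,      Phi = diag(phi),

a single global propagation step that mixes information across all hops
at once.  Per-biomarker risks are then logistic read-outs of Z,

    P_b = sigma(theta_b^T Z),

and all parameters (one shared phi, one theta_b per biomarker) are
trained jointly by full-batch gradient descent on the summed binary
cross-entropy plus an L2 complexity penalty, using analytic gradients
derived by implicit differentiation of the linear solve.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve
from scipy.special import expit

from .datatypes import (
    DEFAULT_BIOMARKERS,
    BiomarkerLabels,
    ExpressionMatrix,
    PPINetwork,
    RiskScores,
    SynergyMatrix,
)

#: Risk scores are clipped into [RISK_CLIP, 1 - RISK_CLIP] before logs.
RISK_CLIP = 1e-12
#: Propagation intensities are projected onto [PHI_FLOOR, inf) after each
#: update; positivity keeps (Phi + L) symmetric positive definite.
PHI_FLOOR = 1e-6


@dataclass
class LaplacianOperator:
    """Symmetric normalized graph Laplacian together with node degrees."""

    matrix: np.ndarray
    degree: np.ndarray


@dataclass
class ModelParams:
    """Fitted model state: shared phi plus one estimation vector per task.

    ``beta`` holds optional per-task covariate weights (the demographic
    extension); ``cov_mean``/``cov_std`` are the standardization moments
    frozen at training time.
    """

    phi: np.ndarray
    theta: dict[str, np.ndarray]
    delta: float = 1e-3
    eta: float = 1e-3
    protein_ids: list[str] | None = None
    beta: dict[str, np.ndarray] | None = None
    cov_mean: np.ndarray | None = None
    cov_std: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.ndim != 1 or np.any(self.phi <= 0):
            raise ValueError("phi must be a strictly positive vector")
        d = self.phi.shape[0]
        for name, vec in self.theta.items():
            arr = np.asarray(vec, dtype=float)
            if arr.shape != (d,):
                raise ValueError(f"theta[{name!r}] must have length {d}")
            self.theta[name] = arr

    @property
    def biomarkers(self) -> list[str]:
        return list(self.theta)


@dataclass
class TrainConfig:
    """Training knobs: optimizer, stopping rule and regularization.

    delta is the L2 penalty weight on ||phi||^2 + sum_b ||theta_b||^2; eta
    the step size.  "adam" (the default, step 0.001) matches the
    experimental setup; "plain-gd" runs the textbook full-batch update.
    ``init_scale`` > 0 draws a small random theta initialization from
    ``seed`` instead of the analytic all-zeros start.
    """

    max_epochs: int = 2000
    tol: float = 1e-6
    optimizer: str = "adam"
    eta: float = 1e-3
    delta: float = 1e-3
    seed: int = 0
    covariates_enabled: bool = False
    init_scale: float = 0.0

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.tol < 0:
            raise ValueError("tol must be >= 0")
        if self.eta <= 0:
            raise ValueError("eta must be > 0")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.optimizer not in ("plain-gd", "adam"):
            raise ValueError("optimizer must be 'plain-gd' or 'adam'")


@dataclass
class FitResult:
    """Outcome of :func:`fit`: parameters, loss trace and training risks."""

    params: ModelParams
    loss_trace: np.ndarray
    risks: RiskScores
    n_epochs: int
    converged: bool


def normalized_laplacian(network: PPINetwork) -> LaplacianOperator:
    """Build L = I - D^{-1/2} W D^{-1/2} from a validated network.

    Isolated nodes (zero degree) contribute identity rows/columns, so the
    Laplacian of an edgeless graph is exactly the identity.  The result is
    symmetric positive semidefinite with spectrum in [0, 2].
    """
    W = network.weights
    deg = W.sum(axis=1)
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(deg > 0, deg, 1.0) ** -0.5
    inv_sqrt[deg == 0] = 0.0
    S = inv_sqrt[:, None] * W * inv_sqrt[None, :]
    L = np.eye(W.shape[0]) - S
    L = 0.5 * (L + L.T)  # kill rounding asymmetry
    return LaplacianOperator(matrix=L, degree=deg)


def _check_phi(phi: np.ndarray, d: int) -> np.ndarray:
    phi = np.asarray(phi, dtype=float)
    if phi.shape != (d,):
        raise ValueError(f"phi must have length {d}, got shape {phi.shape}")
    if np.any(phi <= 0):
        raise ValueError(
            f"phi must be strictly positive (use phi >= {PHI_FLOOR}); "
            f"min entry is {phi.min()}"
        )
    return phi


def _propagation_factor(L: LaplacianOperator, phi: np.ndarray):
    """Cholesky factor of (Phi + L); shared by the solve and both gradients."""
    A = L.matrix + np.diag(phi)
    try:
        return cho_factor(A, lower=True)
    except LinAlgError as exc:  # unreachable for phi > 0, defensive
        raise ValueError(
            f"(Phi + L) is numerically singular; ensure phi >= {PHI_FLOOR}"
        ) from exc


def propagate(
    X: ExpressionMatrix, L: LaplacianOperator, phi: np.ndarray
) -> SynergyMatrix:
    """Closed-form graph propagation Z = (Phi + L)^{-1} Phi X.

    One symmetric positive-definite factorization is reused across all
    sample columns; each participant is propagated independently of the
    others (Z is linear in X, column by column).
    """
    d = X.n_proteins
    phi = _check_phi(phi, d)
    if L.matrix.shape != (d, d):
        raise ValueError("Laplacian shape does not match expression matrix")
    factor = _propagation_factor(L, phi)
    Z = cho_solve(factor, phi[:, None] * X.values)
    return SynergyMatrix(values=Z, protein_ids=X.protein_ids, sample_ids=X.sample_ids)


def estimate_risk(
    Z: np.ndarray | SynergyMatrix,
    theta: np.ndarray,
    covariates: np.ndarray | None = None,
    beta: np.ndarray | None = None,
) -> np.ndarray:
    """Logistic risk read-out sigma(theta^T Z [+ covariates beta]), no intercept."""
    Zv = Z.values if isinstance(Z, SynergyMatrix) else np.asarray(Z, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (Zv.shape[0],):
        raise ValueError(
            f"theta length {theta.shape} does not match {Zv.shape[0]} proteins"
        )
    if (covariates is None) != (beta is None):
        raise ValueError("covariates and beta must be provided together")
    logit = theta @ Zv
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        beta = np.asarray(beta, dtype=float)
        if C.shape != (Zv.shape[1], beta.shape[0]):
            raise ValueError(
                f"covariates shape {C.shape} incompatible with n={Zv.shape[1]} "
                f"and beta length {beta.shape[0]}"
            )
        logit = logit + C @ beta
    return np.clip(expit(logit), RISK_CLIP, 1.0 - RISK_CLIP)


def bce_loss(P: np.ndarray, Y: np.ndarray) -> float:
    """Mean binary cross-entropy -(1/n)[Y^T log P + (1-Y)^T log(1-P)]."""
    P = np.asarray(P, dtype=float)
    Y = np.asarray(Y)
    if not np.isin(Y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    Y = Y.astype(float)
    P = np.clip(P, RISK_CLIP, 1.0 - RISK_CLIP)
    return float(-np.mean(Y * np.log(P) + (1.0 - Y) * np.log1p(-P)))


def total_objective(
    params: ModelParams,
    X: ExpressionMatrix,
    L: LaplacianOperator,
    labels: BiomarkerLabels,
    covariates: np.ndarray | None = None,
) -> float:
    """Summed task losses plus delta (||phi||^2 + sum_b ||theta_b||^2 [+ ||beta_b||^2])."""
    Z = propagate(X, L, params.phi)
    total = 0.0
    reg = float(params.phi @ params.phi)
    for name in labels.biomarkers:
        theta = params.theta[name]
        beta = params.beta[name] if params.beta is not None else None
        P = estimate_risk(Z, theta, covariates if beta is not None else None, beta)
        total += bce_loss(P, labels.labels[name])
        reg += float(theta @ theta)
        if beta is not None:
            reg += float(beta @ beta)
    return total + params.delta * reg


def grad_theta(
    Z: np.ndarray | SynergyMatrix,
    P: np.ndarray,
    Y: np.ndarray,
    theta: np.ndarray,
    delta: float,
) -> np.ndarray:
    """Analytic gradient (1/n) Z (P - Y) + 2 delta theta."""
    Zv = Z.values if isinstance(Z, SynergyMatrix) else np.asarray(Z, dtype=float)
    resid = np.asarray(P, dtype=float) - np.asarray(Y, dtype=float)
    n = Zv.shape[1]
    return Zv @ resid / n + 2.0 * delta * np.asarray(theta, dtype=float)


def grad_phi(
    phi: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    G: np.ndarray,
    factor,
    delta: float,
) -> np.ndarray:
    """Analytic gradient of the objective with respect to phi.

    Implicit differentiation of A Z = Phi X with A = Phi + L gives
    dZ/dphi_i = A^{-1} E_ii (X - Z), so with the loss sensitivity
    G = dL/dZ = (1/n) sum_b theta_b (P_b - Y_b)^T,

        (grad phi)_i = row_i(A^{-1} G) . row_i(X - Z) + 2 delta phi_i.

    ``factor`` is the Cholesky factorization of A produced while solving
    for Z; reusing it makes the gradient one extra triangular solve.
    """
    M = cho_solve(factor, G)
    return np.einsum("ij,ij->i", M, X - Z) + 2.0 * delta * np.asarray(phi, dtype=float)


def _loss_sensitivity(
    theta: dict[str, np.ndarray],
    P: dict[str, np.ndarray],
    Y: dict[str, np.ndarray],
    n: int,
) -> np.ndarray:
    """dL/dZ = (1/n) sum_b theta_b outer (P_b - Y_b)."""
    d = next(iter(theta.values())).shape[0]
    G = np.zeros((d, n))
    for name, th in theta.items():
        G += np.outer(th, P[name] - Y[name])
    return G / n


class _Adam:
    """Minimal ADAM state for one parameter vector."""

    def __init__(self, size: int, eta: float, b1: float = 0.9, b2: float = 0.999):
        self.m = np.zeros(size)
        self.v = np.zeros(size)
        self.t = 0
        self.eta, self.b1, self.b2 = eta, b1, b2

    def step(self, x: np.ndarray, g: np.ndarray) -> np.ndarray:
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * g
        self.v = self.b2 * self.v + (1 - self.b2) * g * g
        mhat = self.m / (1 - self.b1**self.t)
        vhat = self.v / (1 - self.b2**self.t)
        return x - self.eta * mhat / (np.sqrt(vhat) + 1e-8)


def fit(
    X: ExpressionMatrix,
    network: PPINetwork,
    labels: BiomarkerLabels,
    config: TrainConfig | None = None,
    covariates: np.ndarray | None = None,
) -> FitResult:
    """Full-batch joint training of phi and all theta_b (and optional beta_b).

    Every epoch refactorizes (Phi + L) once, propagates, scores all tasks,
    and applies simultaneous updates from the analytic gradients.  phi is
    projected onto [PHI_FLOOR, inf) after each step.  Stops at
    ``max_epochs`` or when the relative change of the objective falls
    below ``tol``.  Deterministic for a given config.
    """
    config = config or TrainConfig()
    if X.protein_ids != network.protein_ids:
        raise ValueError("expression matrix and network protein identifiers differ")
    if X.sample_ids != labels.sample_ids:
        raise ValueError("expression matrix and label sample identifiers differ")
    L = normalized_laplacian(network)
    d, n = X.values.shape
    names = labels.biomarkers
    Y = {b: labels.labels[b].astype(float) for b in names}

    rng = np.random.default_rng(config.seed)
    phi = np.ones(d)
    theta = {
        b: config.init_scale * rng.standard_normal(d)
        if config.init_scale > 0
        else np.zeros(d)
        for b in names
    }
    use_cov = config.covariates_enabled and covariates is not None
    if config.covariates_enabled and covariates is None:
        raise ValueError("covariates_enabled but no covariate matrix supplied")
    C = cov_mean = cov_std = None
    beta: dict[str, np.ndarray] | None = None
    if use_cov:
        C_raw = np.asarray(covariates, dtype=float)
        if C_raw.shape[0] != n:
            raise ValueError(f"covariate rows ({C_raw.shape[0]}) must equal n={n}")
        cov_mean = C_raw.mean(axis=0)
        cov_std = C_raw.std(axis=0, ddof=1)
        cov_std = np.where(cov_std > 0, cov_std, 1.0)
        C = (C_raw - cov_mean) / cov_std
        beta = {b: np.zeros(C.shape[1]) for b in names}

    adam: dict[str, _Adam] = {}
    if config.optimizer == "adam":
        adam["phi"] = _Adam(d, config.eta)
        for b in names:
            adam[f"theta:{b}"] = _Adam(d, config.eta)
            if beta is not None:
                adam[f"beta:{b}"] = _Adam(C.shape[1], config.eta)

    delta, eta = config.delta, config.eta
    trace: list[float] = []
    converged = False
    for epoch in range(config.max_epochs):
        if not np.all(np.isfinite(phi)):
            raise FloatingPointError(
                f"training diverged at epoch {epoch} (non-finite phi); reduce eta"
            )
        factor = _propagation_factor(L, phi)
        Z = cho_solve(factor, phi[:, None] * X.values)
        P: dict[str, np.ndarray] = {}
        loss = 0.0
        with np.errstate(over="ignore"):  # divergence caught via isfinite below
            reg = float(phi @ phi)
            for b in names:
                logit = theta[b] @ Z
                if beta is not None:
                    logit = logit + C @ beta[b]
                P[b] = np.clip(expit(logit), RISK_CLIP, 1.0 - RISK_CLIP)
                loss += bce_loss(P[b], labels.labels[b])
                reg += float(theta[b] @ theta[b])
                if beta is not None:
                    reg += float(beta[b] @ beta[b])
        loss += delta * reg
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"training diverged at epoch {epoch} (non-finite loss); reduce eta"
            )
        trace.append(loss)

        G = _loss_sensitivity(theta, P, Y, n)
        g_phi = grad_phi(phi, X.values, Z, G, factor, delta)
        g_theta = {b: grad_theta(Z, P[b], Y[b], theta[b], delta) for b in names}
        g_beta = (
            {b: C.T @ (P[b] - Y[b]) / n + 2.0 * delta * beta[b] for b in names}
            if beta is not None
            else None
        )

        if config.optimizer == "adam":
            phi = adam["phi"].step(phi, g_phi)
            for b in names:
                theta[b] = adam[f"theta:{b}"].step(theta[b], g_theta[b])
                if beta is not None:
                    beta[b] = adam[f"beta:{b}"].step(beta[b], g_beta[b])
        else:
            phi = phi - eta * g_phi
            for b in names:
                theta[b] = theta[b] - eta * g_theta[b]
                if beta is not None:
                    beta[b] = beta[b] - eta * g_beta[b]
        phi = np.clip(phi, PHI_FLOOR, None)

        if epoch > 0:
            prev, cur = trace[-2], trace[-1]
            if abs(prev - cur) <= config.tol * max(1.0, abs(prev)):
                converged = True
                break

    params = ModelParams(
        phi=phi,
        theta=theta,
        delta=delta,
        eta=eta,
        protein_ids=list(X.protein_ids),
        beta=beta,
        cov_mean=cov_mean,
        cov_std=cov_std,
    )
    risks = predict(params, X, network, covariates=covariates if use_cov else None)
    return FitResult(
        params=params,
        loss_trace=np.asarray(trace),
        risks=risks,
        n_epochs=len(trace),
        converged=converged,
    )


def predict(
    params: ModelParams,
    X_new: ExpressionMatrix,
    network: PPINetwork,
    covariates: np.ndarray | None = None,
) -> RiskScores:
    """Propagate new samples with the trained phi and score every task.

    Propagation mixes proteins within each sample column and never across
    samples, so prediction is leakage-free and per-sample independent.
    """
    if params.protein_ids is not None and X_new.protein_ids != params.protein_ids:
        missing = sorted(set(params.protein_ids) - set(X_new.protein_ids))
        raise ValueError(
            "protein set mismatch between trained model and new data; "
            f"missing or misordered proteins: {missing if missing else 'order differs'}"
        )
    if X_new.protein_ids != network.protein_ids:
        raise ValueError("expression matrix and network protein identifiers differ")
    L = normalized_laplacian(network)
    Z = propagate(X_new, L, params.phi)
    C = None
    if params.beta is not None:
        if covariates is None:
            raise ValueError("model was trained with covariates; none supplied")
        C = (np.asarray(covariates, dtype=float) - params.cov_mean) / params.cov_std
    scores = {
        b: estimate_risk(
            Z,
            params.theta[b],
            C,
            params.beta[b] if params.beta is not None else None,
        )
        for b in params.biomarkers
    }
    return RiskScores(scores=scores, sample_ids=list(X_new.sample_ids))


def iterative_propagate(
    X: ExpressionMatrix,
    L: LaplacianOperator,
    phi: np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 100000,
) -> SynergyMatrix:
    """Fixed-point solver Z <- (Phi + I)^{-1}(Phi X + S Z), S = I - L.

    Converges for any phi > 0 because (Phi + I)^{-1} S is a contraction;
    serves as an independent cross-check of the closed-form solve.
    """
    phi = _check_phi(phi, X.n_proteins)
    S = np.eye(X.n_proteins) - L.matrix
    inv = 1.0 / (phi + 1.0)
    Z = X.values.copy()
    for _ in range(max_iter):
        Z_next = inv[:, None] * (phi[:, None] * X.values + S @ Z)
        if np.max(np.abs(Z_next - Z)) < tol:
            Z = Z_next
            break
        Z = Z_next
    return SynergyMatrix(values=Z, protein_ids=X.protein_ids, sample_ids=X.sample_ids)
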