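"""Continuous-time multistate Markov model for interval-censored panels.

States are the three live sarcopenia stages plus absorbing death.  Each
allowed transition r->s carries a log-linear instantaneous intensity

    q_rs(a, z) = exp(alpha_rs + beta_rs * (a - a0) + gamma_rs . z)

with ``a`` the current age, ``a0`` an age-centering constant (60 y by
default, so alpha is the log rate at age 60) and ``z`` time-constant
covariates.  ``beta_rs > 0`` gives Gompertz-type exponentially
age-increasing rates.  The generator Q(a, z) has these off-diagonal
entries, zero for disallowed moves, diagonal minus the row sum, and an
all-zero death row.

Transition probabilities over an interval are computed by the standard
piecewise-constant approximation: the interval is cut into sub-steps of
length ``approx_step`` (last one partial), Q is frozen at each
sub-step's start age, and P is the product of the sub-step matrix
exponentials.

The panel likelihood multiplies, per subject, one factor per
consecutive-observation interval:

* live -> live over dt:         P_{r,s}(dt)
* live -> death at exact age t: sum over live s of P_{r,s}(dt) q_{s,dead}(t)

Interval-censored deaths are resolved upstream to their midpoint-imputed
age and enter as exactly timed.  Maximisation is quasi-Newton (BFGS) on
the unconstrained (alpha, beta, gamma) scale with finite-difference
gradients; the covariance is the inverse observed information from a
central-difference Hessian.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.optimize

from ._linalg import expm_batch
from .cohort import PanelDataset

__all__ = [
    "TransitionStructure",
    "DEFAULT_STRUCTURE",
    "IntensityModel",
    "ParamLayout",
    "FittedModel",
    "build_q",
    "transition_probability",
    "panel_loglik",
    "loglik_breakdown",
    "crude_init",
    "fit_msm",
]

logger = logging.getLogger(__name__)

# Exponent clip: keeps intermediate rates finite while the optimizer
# explores; exp(30)/y is far beyond any plausible intensity.
_ETA_MAX = 30.0
_LOG_FLOOR = 1e-300


@dataclass(frozen=True)
class TransitionStructure:
    """Which instantaneous transitions exist.

    ``transitions`` is an ordered tuple of 1-based (from, to) pairs;
    ``dead_state`` is absorbing (no transitions out of it).
    """

    transitions: tuple[tuple[int, int], ...]
    n_states: int = 4
    dead_state: int = 4

    def __post_init__(self):
        seen = set()
        for r, s in self.transitions:
            if not (1 <= r <= self.n_states and 1 <= s <= self.n_states):
                raise ValueError(f"transition {(r, s)} outside 1..{self.n_states}")
            if r == s:
                raise ValueError("self-transitions are not parameters")
            if r == self.dead_state:
                raise ValueError("death state is absorbing; no exits allowed")
            if (r, s) in seen:
                raise ValueError(f"duplicate transition {(r, s)}")
            seen.add((r, s))

    @property
    def n_transitions(self) -> int:
        return len(self.transitions)

    @property
    def live_states(self) -> list[int]:
        return [s for s in range(1, self.n_states + 1) if s != self.dead_state]

    def labels(self) -> list[str]:
        return [f"{r}->{s}" for r, s in self.transitions]


def adjacent_structure(direct_1_3: bool = False) -> TransitionStructure:
    """The default severity-ladder structure.

    Adjacent-stage moves 1<->2 and 2<->3 plus death from every live
    state; observed two-year 1->3 / 3->1 jumps are explained through the
    unobserved intermediate stage.  ``direct_1_3=True`` adds explicit
    1<->3 intensities.
    """
    trans = [(1, 2), (2, 1), (2, 3), (3, 2), (1, 4), (2, 4), (3, 4)]
    if direct_1_3:
        trans = trans[:4] + [(1, 3), (3, 1)] + trans[4:]
    return TransitionStructure(tuple(trans))


DEFAULT_STRUCTURE = adjacent_structure()


@dataclass
class IntensityModel:
    """Log-linear transition-intensity model (see module docstring)."""

    structure: TransitionStructure
    alpha: np.ndarray  # (K,) baseline log intensities at the centering age
    beta: np.ndarray | None = None  # (K,) per-year-of-age log slopes
    gamma: np.ndarray | None = None  # (K, p) covariate log effects
    age_center: float = 60.0
    covariate_names: tuple[str, ...] = ()

    def __post_init__(self):
        k = self.structure.n_transitions
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.shape != (k,):
            raise ValueError(f"alpha must have shape ({k},)")
        if self.beta is None:
            self.beta = np.zeros(k)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (k,):
            raise ValueError(f"beta must have shape ({k},)")
        if self.gamma is None:
            self.gamma = np.zeros((k, len(self.covariate_names)))
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.gamma.ndim != 2 or self.gamma.shape[0] != k:
            raise ValueError(f"gamma must have shape ({k}, p)")
        if len(self.covariate_names) not in (0, self.gamma.shape[1]):
            raise ValueError("covariate_names length must match gamma columns")
        for arr in (self.alpha, self.beta, self.gamma):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite model parameters")

    @property
    def n_covariates(self) -> int:
        return self.gamma.shape[1]

    def rates(self, ages, covariates=None) -> np.ndarray:
        """Per-transition intensities, shape (B, K) for B ages."""
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        eta = self.alpha[None, :] + np.outer(ages - self.age_center, self.beta)
        if self.n_covariates:
            z = np.asarray(covariates, dtype=float)
            if z.ndim == 1:
                z = np.broadcast_to(z, (ages.size, z.size))
            eta = eta + z @ self.gamma.T
        return np.exp(np.clip(eta, -700.0, _ETA_MAX))

    def q_batch(self, ages, covariates=None) -> np.ndarray:
        """Generator matrices Q(a, z), shape (B, n, n)."""
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        rates = self.rates(ages, covariates)
        n = self.structure.n_states
        q = np.zeros((ages.size, n, n))
        for k, (r, s) in enumerate(self.structure.transitions):
            q[:, r - 1, s - 1] = rates[:, k]
        rows = np.arange(n)
        q[:, rows, rows] -= q.sum(axis=2)
        return q

    def intensity_matrix(self, age: float, covariates=None) -> np.ndarray:
        """Single generator matrix Q(age, z)."""
        return self.q_batch([age], covariates)[0]


def build_q(model: IntensityModel, age: float, covariates=None) -> np.ndarray:
    """Intensity (generator) matrix at one age; functional alias."""
    return model.intensity_matrix(age, covariates)


def _substep_plan(dt: np.ndarray, approx_step: float):
    """Split intervals into sub-steps of length ``approx_step``.

    Returns (n_sub, offsets, rel_start, h_flat, owner): per-interval
    sub-step counts, flat start offsets, each flat sub-step's start time
    relative to its interval, its length, and its interval index.
    """
    if approx_step <= 0:
        raise ValueError("approx_step must be positive")
    n_sub = np.maximum(1, np.ceil(dt / approx_step - 1e-12).astype(int))
    offsets = np.concatenate([[0], np.cumsum(n_sub)[:-1]])
    total = int(n_sub.sum())
    owner = np.repeat(np.arange(dt.size), n_sub)
    pos = np.arange(total) - offsets[owner]
    rel_start = pos * approx_step
    h_flat = np.minimum(approx_step, dt[owner] - rel_start)
    return n_sub, offsets, rel_start, h_flat, owner


def _interval_probs(
    model: IntensityModel,
    age0: np.ndarray,
    dt: np.ndarray,
    covariates: np.ndarray | None,
    approx_step: float,
) -> np.ndarray:
    """Transition-probability matrices for a batch of intervals."""
    age0 = np.asarray(age0, dtype=float)
    dt = np.asarray(dt, dtype=float)
    if np.any(dt < 0):
        raise ValueError("negative interval length")
    n = model.structure.n_states
    n_iv = age0.size
    p = np.broadcast_to(np.eye(n), (n_iv, n, n)).copy()
    pos_mask = dt > 0
    if not pos_mask.any():
        return p
    n_sub, offsets, rel_start, h_flat, owner = _substep_plan(dt, approx_step)
    z_flat = None
    if model.n_covariates:
        z_flat = np.asarray(covariates, dtype=float)[owner]
    q = model.q_batch(age0[owner] + rel_start, z_flat)
    e = expm_batch(q * h_flat[:, None, None])
    max_sub = int(n_sub.max())
    for k in range(max_sub):
        m = n_sub > k
        p[m] = p[m] @ e[offsets[m] + k]
    return p


def transition_probability(
    model: IntensityModel,
    age0: float,
    dt: float,
    covariates=None,
    approx_step: float = 1.0,
) -> np.ndarray:
    """Row-stochastic transition matrix over [age0, age0 + dt].

    Piecewise-constant in age: Q frozen at each ``approx_step``
    sub-interval's start age, P the product of sub-interval matrix
    exponentials.  ``dt == 0`` returns the identity.
    """
    if dt < 0:
        raise ValueError("dt must be nonnegative")
    z = None
    if model.n_covariates:
        z = np.asarray(covariates, dtype=float)[None, :]
    return _interval_probs(
        model, np.array([age0]), np.array([float(dt)]), z, approx_step
    )[0]


def _interval_arrays(data: PanelDataset, covariate_names: Sequence[str]):
    iv = data.intervals()
    age0 = iv["age0"].to_numpy(dtype=float)
    dt = iv["dt"].to_numpy(dtype=float)
    r = iv["from_state"].to_numpy(dtype=int)
    s = iv["to_state"].to_numpy(dtype=int)
    z = None
    if covariate_names:
        z = iv[list(covariate_names)].to_numpy(dtype=float)
    return iv, age0, dt, r, s, z


def _interval_likelihoods(
    model: IntensityModel, data: PanelDataset, approx_step: float
):
    """Per-interval likelihood contributions (not yet logged)."""
    iv, age0, dt, r, s, z = _interval_arrays(data, model.covariate_names)
    dead = data.dead_state
    if np.any(r == dead):
        raise ValueError("interval starting in the death state")
    p = _interval_probs(model, age0, dt, z, approx_step)
    live_idx = np.array([st - 1 for st in model.structure.live_states])
    contrib = np.empty(len(iv))
    is_death = s == dead
    rows = np.arange(len(iv))
    contrib[~is_death] = p[rows[~is_death], r[~is_death] - 1, s[~is_death] - 1]
    if is_death.any():
        # density of an exactly timed death: sum over the live state
        # occupied just before death of P_{r,s}(dt) * q_{s,dead}(t_death)
        d = rows[is_death]
        zd = z[d] if z is not None else None
        q_death = model.q_batch(age0[d] + dt[d], zd)[:, :, dead - 1]
        contrib[d] = np.einsum(
            "is,is->i", p[d, r[d] - 1][:, live_idx], q_death[:, live_idx]
        )
    return iv, contrib


def panel_loglik(
    model: IntensityModel, data: PanelDataset, approx_step: float = 1.0
) -> float:
    """Log-likelihood of a validated panel under ``model``.

    Zero-probability observed transitions contribute -inf; use
    :func:`loglik_breakdown` to identify the offending records.
    """
    _, contrib = _interval_likelihoods(model, data, approx_step)
    if np.any(contrib <= 0):
        return -np.inf
    return float(np.sum(np.log(contrib)))


def loglik_breakdown(
    model: IntensityModel, data: PanelDataset, approx_step: float = 1.0
):
    """Per-interval log contributions, flagging impossible transitions.

    Returns the intervals frame with ``likelihood`` and ``loglik``
    columns; rows with nonpositive likelihood are the records whose
    observed transition has probability zero under the structure.
    """
    iv, contrib = _interval_likelihoods(model, data, approx_step)
    iv = iv.copy()
    iv["likelihood"] = contrib
    iv["loglik"] = np.log(np.maximum(contrib, _LOG_FLOOR))
    return iv


@dataclass(frozen=True)
class ParamLayout:
    """Packing of free parameters into a flat vector.

    Order: alpha (K), then beta (K) if the age effect is on, then gamma
    row-major (K * p).
    """

    structure: TransitionStructure
    age_effect: bool = True
    covariate_names: tuple[str, ...] = ()
    age_center: float = 60.0

    @property
    def n_params(self) -> int:
        k = self.structure.n_transitions
        return k * (1 + int(self.age_effect) + len(self.covariate_names))

    def names(self) -> list[str]:
        labels = self.structure.labels()
        out = [f"alpha[{t}]" for t in labels]
        if self.age_effect:
            out += [f"beta[{t}]" for t in labels]
        for c in self.covariate_names:
            out += [f"gamma[{t}]:{c}" for t in labels]
        return out

    def unpack(self, theta: np.ndarray) -> IntensityModel:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_params,):
            raise ValueError(f"expected {self.n_params} parameters")
        k = self.structure.n_transitions
        p = len(self.covariate_names)
        alpha = theta[:k]
        pos = k
        beta = None
        if self.age_effect:
            beta = theta[pos : pos + k]
            pos += k
        gamma = theta[pos:].reshape(p, k).T if p else None
        return IntensityModel(
            self.structure,
            alpha,
            beta,
            gamma,
            age_center=self.age_center,
            covariate_names=self.covariate_names,
        )

    def pack(self, model: IntensityModel) -> np.ndarray:
        parts = [model.alpha]
        if self.age_effect:
            parts.append(model.beta)
        if self.covariate_names:
            parts.append(model.gamma.T.ravel())
        return np.concatenate(parts)


def crude_init(
    data: PanelDataset,
    structure: TransitionStructure,
    floor: float = np.exp(-8.0),
) -> np.ndarray:
    """Crude initial log intensities: transition counts / person-time.

    Counts observed interval transitions that coincide with an allowed
    instantaneous move; person-time at risk in state r is the summed
    interval length started in r.  Unobserved transitions are floored at
    ``floor`` per year (default exp(-8)).
    """
    iv = data.intervals()
    r = iv["from_state"].to_numpy(dtype=int)
    s = iv["to_state"].to_numpy(dtype=int)
    dt = iv["dt"].to_numpy(dtype=float)
    alpha = np.empty(structure.n_transitions)
    unobserved = []
    for k, (a, b) in enumerate(structure.transitions):
        count = int(np.sum((r == a) & (s == b)))
        time = float(dt[r == a].sum())
        if count == 0:
            unobserved.append((a, b))
        rate = count / time if time > 0 else 0.0
        alpha[k] = np.log(max(rate, floor))
    if unobserved:
        warnings.warn(
            "no observed interval transition for "
            + ", ".join(f"{a}->{b}" for a, b in unobserved)
            + "; these intensities may be weakly identified",
            stacklevel=2,
        )
    return alpha


def _fd_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    p = x.size
    h = rel_step * np.maximum(np.abs(x), 1.0)
    hess = np.empty((p, p))
    f0 = f(x)

    def fp(i, hi, j=None, hj=0.0):
        xx = x.copy()
        xx[i] += hi
        if j is not None:
            xx[j] += hj
        return f(xx)

    for i in range(p):
        hess[i, i] = (fp(i, h[i]) + fp(i, -h[i]) - 2.0 * f0) / h[i] ** 2
        for j in range(i + 1, p):
            v = (
                fp(i, h[i], j, h[j])
                - fp(i, h[i], j, -h[j])
                - fp(i, -h[i], j, h[j])
                + fp(i, -h[i], j, -h[j])
            ) / (4.0 * h[i] * h[j])
            hess[i, j] = hess[j, i] = v
    return hess


@dataclass
class FittedModel:
    """Maximum-likelihood fit of an :class:`IntensityModel`."""

    model: IntensityModel
    layout: ParamLayout
    params: np.ndarray
    cov: np.ndarray | None
    loglik: float
    converged: bool
    n_iter: int
    n_evals: int
    approx_step: float
    message: str = ""

    @property
    def param_names(self) -> list[str]:
        return self.layout.names()

    def se(self) -> np.ndarray:
        if self.cov is None:
            raise ValueError("fit has no covariance matrix")
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def model_from_params(self, theta: np.ndarray) -> IntensityModel:
        """Rebuild an intensity model from a parameter vector (bootstrap)."""
        return self.layout.unpack(theta)

    def to_json(self, path) -> None:
        payload = {
            "transitions": list(map(list, self.layout.structure.transitions)),
            "n_states": self.layout.structure.n_states,
            "dead_state": self.layout.structure.dead_state,
            "age_effect": self.layout.age_effect,
            "covariate_names": list(self.layout.covariate_names),
            "age_center": self.layout.age_center,
            "param_names": self.param_names,
            "params": self.params.tolist(),
            "cov": None if self.cov is None else self.cov.tolist(),
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "n_evals": self.n_evals,
            "approx_step": self.approx_step,
            "message": self.message,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "FittedModel":
        with open(path) as fh:
            d = json.load(fh)
        structure = TransitionStructure(
            tuple(map(tuple, d["transitions"])),
            n_states=d["n_states"],
            dead_state=d["dead_state"],
        )
        layout = ParamLayout(
            structure,
            age_effect=d["age_effect"],
            covariate_names=tuple(d["covariate_names"]),
            age_center=d["age_center"],
        )
        params = np.asarray(d["params"], dtype=float)
        cov = None if d["cov"] is None else np.asarray(d["cov"], dtype=float)
        return cls(
            model=layout.unpack(params),
            layout=layout,
            params=params,
            cov=cov,
            loglik=d["loglik"],
            converged=d["converged"],
            n_iter=d["n_iter"],
            n_evals=d["n_evals"],
            approx_step=d["approx_step"],
            message=d.get("message", ""),
        )


def fit_msm(
    data: PanelDataset,
    structure: TransitionStructure | None = None,
    covariates: Sequence[str] = (),
    age_effect: bool = True,
    init: np.ndarray | None = None,
    approx_step: float = 1.0,
    age_center: float = 60.0,
    gtol: float = 5e-4,
    maxiter: int = 500,
    compute_covariance: bool = True,
) -> FittedModel:
    """Fit the multistate model by maximum likelihood.

    ``init`` may be a full parameter vector (layout order); by default
    alphas start at the crude observed rates and slopes at zero.
    Non-convergence is flagged on the result, never silent.
    """
    structure = structure or DEFAULT_STRUCTURE
    layout = ParamLayout(
        structure,
        age_effect=age_effect,
        covariate_names=tuple(covariates),
        age_center=age_center,
    )
    if init is None:
        theta0 = np.zeros(layout.n_params)
        theta0[: structure.n_transitions] = crude_init(data, structure)
    else:
        theta0 = np.asarray(init, dtype=float)
        if theta0.shape != (layout.n_params,):
            raise ValueError(f"init must have {layout.n_params} entries")

    n_evals = 0

    def negloglik(theta):
        nonlocal n_evals
        n_evals += 1
        ll = panel_loglik(layout.unpack(theta), data, approx_step)
        if not np.isfinite(ll):
            return 1e12
        return -ll

    res = scipy.optimize.minimize(
        negloglik,
        theta0,
        method="BFGS",
        options={"gtol": gtol, "maxiter": maxiter},
    )
    theta = res.x
    loglik = -float(res.fun)
    converged = bool(res.success)
    if not converged:
        # BFGS often reports precision loss at a genuine optimum when
        # gradients come from finite differences; accept if the gradient
        # is small on the likelihood scale.
        gnorm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
        converged = gnorm < 50 * gtol
        if not converged:
            logger.warning("fit_msm did not converge: %s", res.message)

    cov = None
    if compute_covariance:
        hess = _fd_hessian(negloglik, theta)
        # observed information = Hessian of -loglik at the MLE
        cov = np.linalg.pinv(hess)
        cov = 0.5 * (cov + cov.T)
        eigmin = float(np.linalg.eigvalsh(cov).min())
        if eigmin < -1e-8:
            warnings.warn(
                "covariance not positive semi-definite at the optimum "
                f"(min eigenvalue {eigmin:.2e}); optimum may be on a boundary",
                stacklevel=2,
            )
    return FittedModel(
        model=layout.unpack(theta),
        layout=layout,
        params=theta,
        cov=cov,
        loglik=loglik,
        converged=converged,
        n_iter=int(res.nit),
        n_evals=n_evals,
        approx_step=approx_step,
        message=str(res.message),
    )
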