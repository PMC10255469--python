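"""Recurrent network with Levenberg-Marquardt training.

The network is a single recurrent tanh layer (stackable in principle, but a
shallow wide layer is the default reading of the reference configuration)::

    a_t = tanh(delay_scale * W_aa @ a_{t-1} + W_ax @ x_t + b_a)
    y_t = tanh(W_ya @ a_{t-1} + b_y)        # output fed from the previous state

``delay_scale`` (default 0.01) damps the recurrent term — the system is
nearly static, which suits trials that are mutually independent.  The output
equation as written reads the *previous* hidden state; ``output_from``
switches to the more common current-state convention when wanted.

Training is full-batch damped least squares.  With residual weights
``W_ii = 1/sigma_i**2``, cost ``X² = (y - ŷ)ᵀ W (y - ŷ)``, each step solves

    (Jᵀ W J + λI) h = Jᵀ W (y - ŷ)

and tentatively applies ``p + h``: accepted (λ /= adapt) if the cost
strictly decreases, rejected and retried with λ *= adapt otherwise.  Small λ
approaches a Gauss-Newton update, large λ a scaled gradient-descent step.
The Jacobian J = ∂ŷ/∂p is exact, computed by real-time recurrent learning
(forward sensitivity propagation through time), block-wise per parameter
matrix so that structurally zero blocks cost nothing.

Parameters are flattened in fixed order: W_ax (row-major), W_aa, W_ya,
b_a, b_y.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import linalg

from .exceptions import ConvergenceError, PreconditionError, RangeError, SchemaError

__all__ = [
    "RNNParams",
    "LMConfig",
    "LMState",
    "rnn_forward",
    "as_static_sequences",
    "predict_last",
    "chi_square",
    "jacobian",
    "lm_step",
    "lm_fit",
    "train",
    "save_params",
    "load_params",
]


@dataclass
class RNNParams:
    """Weights, biases and structural settings of one recurrent layer."""

    W_ax: np.ndarray  # (n_hidden, n_input)
    W_aa: np.ndarray  # (n_hidden, n_hidden)
    W_ya: np.ndarray  # (n_output, n_hidden)
    b_a: np.ndarray   # (n_hidden,)
    b_y: np.ndarray   # (n_output,)
    delay_scale: float = 0.01
    output_from: str = "previous"  # previous | current

    def __post_init__(self):
        self.W_ax = np.asarray(self.W_ax, dtype=float)
        self.W_aa = np.asarray(self.W_aa, dtype=float)
        self.W_ya = np.asarray(self.W_ya, dtype=float)
        self.b_a = np.asarray(self.b_a, dtype=float)
        self.b_y = np.asarray(self.b_y, dtype=float)
        nh = self.W_ax.shape[0]
        if self.W_aa.shape != (nh, nh) or self.W_ya.shape[1] != nh:
            raise SchemaError("inconsistent weight shapes")
        if self.b_a.shape != (nh,) or self.b_y.shape != (self.W_ya.shape[0],):
            raise SchemaError("inconsistent bias shapes")
        if self.output_from not in ("previous", "current"):
            raise SchemaError("output_from must be 'previous' or 'current'")
        for w in (self.W_ax, self.W_aa, self.W_ya, self.b_a, self.b_y):
            if not np.all(np.isfinite(w)):
                raise SchemaError("non-finite parameter values")

    @classmethod
    def init(
        cls,
        n_input: int,
        n_hidden: int = 80,
        n_output: int = 1,
        seed: int | None = None,
        delay_scale: float = 0.01,
        output_from: str = "previous",
    ) -> "RNNParams":
        """Fresh parameters with weights and biases uniform in [-0.5, +0.5]."""
        rng = np.random.default_rng(seed)
        u = lambda *shape: rng.uniform(-0.5, 0.5, size=shape)
        return cls(
            W_ax=u(n_hidden, n_input),
            W_aa=u(n_hidden, n_hidden),
            W_ya=u(n_output, n_hidden),
            b_a=u(n_hidden),
            b_y=u(n_output),
            delay_scale=delay_scale,
            output_from=output_from,
        )

    @property
    def n_input(self) -> int:
        return self.W_ax.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.W_ax.shape[0]

    @property
    def n_output(self) -> int:
        return self.W_ya.shape[0]

    @property
    def n_params(self) -> int:
        return self.W_ax.size + self.W_aa.size + self.W_ya.size + self.b_a.size + self.b_y.size

    # flattening order: W_ax, W_aa, W_ya, b_a, b_y (all row-major)
    def flatten(self) -> np.ndarray:
        return np.concatenate(
            [self.W_ax.ravel(), self.W_aa.ravel(), self.W_ya.ravel(),
             self.b_a.ravel(), self.b_y.ravel()]
        )

    def block_slices(self) -> dict[str, slice]:
        sizes = {
            "W_ax": self.W_ax.size, "W_aa": self.W_aa.size,
            "W_ya": self.W_ya.size, "b_a": self.b_a.size, "b_y": self.b_y.size,
        }
        out, off = {}, 0
        for name, size in sizes.items():
            out[name] = slice(off, off + size)
            off += size
        return out

    def with_flat(self, p: np.ndarray) -> "RNNParams":
        p = np.asarray(p, dtype=float)
        if p.size != self.n_params:
            raise SchemaError("flat parameter vector has wrong length")
        s = self.block_slices()
        return replace(
            self,
            W_ax=p[s["W_ax"]].reshape(self.W_ax.shape),
            W_aa=p[s["W_aa"]].reshape(self.W_aa.shape),
            W_ya=p[s["W_ya"]].reshape(self.W_ya.shape),
            b_a=p[s["b_a"]].copy(),
            b_y=p[s["b_y"]].copy(),
        )


@dataclass
class LMConfig:
    """Levenberg-Marquardt settings (reference configuration defaults)."""

    lambda0: float = 3.0     # initial damping factor
    adapt: float = 10.0      # damping multiplier / divisor
    epochs: int = 8          # outer passes (one fresh Jacobian each)
    E_tol: float = 1e-10     # stop when the cost falls at or below this
    sigma: float = 1.0       # per-observation measurement error sigma_yi
    max_tries: int = 12      # damping retries per epoch before giving up
    lambda_max: float = 1e12

    def __post_init__(self):
        if self.lambda0 <= 0:
            raise RangeError("lambda0 must be positive")
        if self.adapt <= 1:
            raise RangeError("adapt must exceed 1")
        if self.epochs < 1:
            raise RangeError("epochs must be >= 1")
        if self.sigma <= 0:
            raise RangeError("sigma must be positive")


@dataclass
class LMState:
    """Current parameter vector, damping and cost, with step history.

    ``history`` records one entry per attempted step:
    ``(chi2_after, lambda_after, accepted)``.  The cost over accepted steps
    is non-increasing by construction.
    """

    p: np.ndarray
    lam: float
    chi2: float
    history: list[tuple[float, float, bool]] = field(default_factory=list)

    @property
    def accepted_chi2(self) -> list[float]:
        return [c for c, _, acc in self.history if acc]


# ---------------------------------------------------------------------------
# Forward pass
# ---------------------------------------------------------------------------

def _forward_batch(params: RNNParams, X: np.ndarray):
    """Run (n, T, n_input) sequences; returns A (n, T+1, nh) incl. a_0 = 0
    and Y (n, T, n_output)."""
    n, T, ni = X.shape
    if ni != params.n_input:
        raise SchemaError(f"input size {ni} != expected {params.n_input}")
    nh, no = params.n_hidden, params.n_output
    A = np.zeros((n, T + 1, nh))
    Y = np.zeros((n, T, no))
    for t in range(1, T + 1):
        pre = (
            params.delay_scale * A[:, t - 1] @ params.W_aa.T
            + X[:, t - 1] @ params.W_ax.T
            + params.b_a
        )
        A[:, t] = np.tanh(pre)
        a_out = A[:, t - 1] if params.output_from == "previous" else A[:, t]
        Y[:, t - 1] = np.tanh(a_out @ params.W_ya.T + params.b_y)
    return A, Y


def rnn_forward(params: RNNParams, X: np.ndarray):
    """Forward pass over one sequence.

    Parameters
    ----------
    X : ndarray, shape (T, n_input)
        Input sequence; the initial hidden state a_0 is zero.

    Returns
    -------
    Y : ndarray, shape (T, n_output)
        tanh outputs, bounded in (-1, 1).
    A : ndarray, shape (T + 1, n_hidden)
        Hidden states including a_0.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise SchemaError("X must be (T, n_input)")
    A, Y = _forward_batch(params, X[None])
    return Y[0], A[0]


def as_static_sequences(F: np.ndarray) -> np.ndarray:
    """Present feature vectors as two-step sequences [x, 0].

    With the output fed from the previous hidden state, the second step's
    output tanh(W_ya a_1 + b_y) is the network's response to x — the
    static (one-fragment-in, one-score-out) operating mode.
    """
    F = np.atleast_2d(np.asarray(F, dtype=float))
    n, d = F.shape
    X = np.zeros((n, 2, d))
    X[:, 0] = F
    return X


def predict_last(params: RNNParams, sequences: np.ndarray) -> np.ndarray:
    """Final-timestep scalar output per sequence -> (n,)."""
    X = _check_sequences(sequences, params)
    _, Y = _forward_batch(params, X)
    return Y[:, -1, 0]


def chi_square(y, yhat, sigma=1.0) -> float:
    """Weighted squared error X² = sum(((y_i - yhat_i)/sigma_i)**2)."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise SchemaError("target/output length mismatch")
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise RangeError("sigma must be positive")
    return float(np.sum(((y - yhat) / sigma) ** 2))


# ---------------------------------------------------------------------------
# RTRL Jacobian
# ---------------------------------------------------------------------------

def _check_sequences(sequences, params: RNNParams) -> np.ndarray:
    X = np.asarray(sequences, dtype=float)
    if X.ndim == 2:  # single sequence
        X = X[None]
    if X.ndim != 3 or X.shape[2] != params.n_input:
        raise SchemaError("sequences must be (n, T, n_input)")
    return X


def jacobian(
    params: RNNParams,
    sequences: np.ndarray,
    obs: str = "last",
    chunk: int = 64,
):
    """Exact Jacobian J[i, j] = dyhat_i/dp_j by real-time recurrent learning.

    Sensitivities of the hidden state are propagated forward in time,

        S_t = diag(1 - a_t²) (delay_scale * W_aa @ S_{t-1} + U_t),

    block-wise per parameter matrix (a block whose sensitivity is
    structurally zero — e.g. W_aa when only the first hidden state is ever
    read — is skipped entirely).  Sequences are processed in chunks to bound
    memory.

    Parameters
    ----------
    obs : {'last', 'all'}
        Which outputs form the observation vector: the final timestep of
        each sequence, or every timestep (sequence-major order).

    Returns
    -------
    J : ndarray, (n_observations, n_params)
    yhat : ndarray, (n_observations,)
        Outputs at the observed timesteps (n_output is 1 per observation
        row times the output width; rows are (sequence, time, output)).
    """
    if obs not in ("last", "all"):
        raise SchemaError("obs must be 'last' or 'all'")
    X_all = _check_sequences(sequences, params)
    n_all, T, ni = X_all.shape
    nh, no = params.n_hidden, params.n_output
    npar = params.n_params
    slices = params.block_slices()
    rows_per_seq = no * (T if obs == "all" else 1)
    J = np.zeros((n_all * rows_per_seq, npar))
    yhat = np.zeros(n_all * rows_per_seq)
    if no != 1:
        # rows would need an extra output axis; the pipeline only uses
        # single-output networks and small nets in tests
        raise SchemaError("jacobian supports n_output == 1")

    delay = params.delay_scale
    ar = np.arange(nh)
    obs_ts = list(range(1, T + 1)) if obs == "all" else [T]

    for lo in range(0, n_all, chunk):
        X = X_all[lo:lo + chunk]
        n = X.shape[0]
        A, Y = _forward_batch(params, X)
        row0 = lo * rows_per_seq

        # which hidden-state indices are read by observed outputs
        s_of_t = (lambda t: t - 1) if params.output_from == "previous" else (lambda t: t)
        needed = {s_of_t(t) for t in obs_ts}
        max_needed = max(needed)

        for name in ("W_ax", "W_aa", "b_a"):
            S = None  # (n, nh, nb) sensitivities of a_t for this block; None == all zero
            S_at: dict[int, np.ndarray | None] = {0: None}
            for t in range(1, max_needed + 1):
                a_t = A[:, t]
                a_prev = A[:, t - 1]
                if S is not None:
                    M = delay * np.einsum("hk,nkp->nhp", params.W_aa, S)
                else:
                    M = None
                if name == "W_ax":
                    if M is None:
                        M = np.zeros((n, nh, nh * ni))
                    V = M.reshape(n, nh, nh, ni)
                    V[:, ar, ar, :] += X[:, t - 1][:, None, :]
                elif name == "W_aa":
                    if np.any(a_prev):
                        if M is None:
                            M = np.zeros((n, nh, nh * nh))
                        V = M.reshape(n, nh, nh, nh)
                        V[:, ar, ar, :] += delay * a_prev[:, None, :]
                else:  # b_a
                    if M is None:
                        M = np.zeros((n, nh, nh))
                    M[:, ar, ar] += 1.0
                S = None if M is None else (1.0 - a_t ** 2)[:, :, None] * M
                if t in needed:
                    S_at[t] = S
            for k, t in enumerate(obs_ts):
                s_idx = s_of_t(t)
                S_s = S_at.get(s_idx)
                if S_s is None:
                    continue
                gy = (1.0 - Y[:, t - 1, 0] ** 2)  # (n,)
                G = gy[:, None] * np.einsum("h,nhp->np", params.W_ya[0], S_s)
                if obs == "all":
                    J[row0 + np.arange(n) * rows_per_seq + k, slices[name]] = G
                else:
                    J[row0:row0 + n, slices[name]] = G

        # output-side blocks: W_ya and b_y (no recurrence through a)
        for k, t in enumerate(obs_ts):
            s_idx = t - 1 if params.output_from == "previous" else t
            a_s = A[:, s_idx]
            gy = (1.0 - Y[:, t - 1, 0] ** 2)
            rows = (row0 + np.arange(n) * rows_per_seq + k) if obs == "all" else slice(row0, row0 + n)
            J[rows, slices["W_ya"]] = gy[:, None] * a_s
            J[rows, slices["b_y"]] = gy[:, None]
            yhat[rows] = Y[:, t - 1, 0]
    return J, yhat


# ---------------------------------------------------------------------------
# Levenberg-Marquardt
# ---------------------------------------------------------------------------

def lm_step(
    state: LMState,
    J: np.ndarray,
    residuals: np.ndarray,
    config: LMConfig,
    evaluate: Callable[[np.ndarray], float],
) -> LMState:
    """One damped least-squares step.

    Solves ``(JᵀWJ + λI) h = JᵀW r`` (W = I/sigma², r = y - ŷ), tentatively
    applies ``p + h`` and accepts (λ /= adapt) iff ``evaluate(p + h)``
    strictly decreases the cost; otherwise the parameters are restored and
    λ *= adapt.  Columns of J that are identically zero are excluded from
    the solve (their update is zero anyway).
    """
    r = np.asarray(residuals, dtype=float).ravel()
    if J.shape[0] != r.size:
        raise SchemaError("Jacobian/residual row mismatch")
    w = 1.0 / config.sigma ** 2
    active = np.flatnonzero(np.any(J != 0.0, axis=0))
    h = np.zeros(J.shape[1])
    if active.size:
        Ja = J[:, active]
        m = Ja.shape[0]
        try:
            if m < active.size:
                # dual (observation-space) solve via the push-through
                # identity: (wJᵀJ + λI)⁻¹ wJᵀr == Jᵀ(JJᵀ + (λ/w)I)⁻¹ r
                B = Ja @ Ja.T
                B[np.diag_indices_from(B)] += state.lam / w
                h[active] = Ja.T @ linalg.solve(B, r, assume_a="pos")
            else:
                Amat = w * (Ja.T @ Ja)
                Amat[np.diag_indices_from(Amat)] += state.lam
                rhs = w * (Ja.T @ r)
                h[active] = linalg.solve(Amat, rhs, assume_a="pos")
        except linalg.LinAlgError:
            Amat = w * (Ja.T @ Ja)
            Amat[np.diag_indices_from(Amat)] += state.lam
            rhs = w * (Ja.T @ r)
            h[active] = np.linalg.lstsq(Amat, rhs, rcond=None)[0]
    if not np.any(h):
        # zero residual projection: nothing to try, leave the state as is
        state.history.append((state.chi2, state.lam, False))
        return state
    p_new = state.p + h
    chi2_new = evaluate(p_new)
    if np.isfinite(chi2_new) and chi2_new < state.chi2:
        state.p = p_new
        state.chi2 = chi2_new
        state.lam = state.lam / config.adapt
        state.history.append((chi2_new, state.lam, True))
    else:
        state.lam = state.lam * config.adapt
        state.history.append((state.chi2, state.lam, False))
    return state


def lm_fit(
    p0: np.ndarray,
    residual_fn: Callable[[np.ndarray], np.ndarray],
    jac_fn: Callable[[np.ndarray], np.ndarray],
    config: LMConfig = LMConfig(),
) -> LMState:
    """Full-batch LM driver over a generic residual model.

    Each epoch computes one fresh Jacobian at the current parameters and
    retries the damped step (λ *= adapt on rejection) until a step is
    accepted or the retry budget / λ ceiling is hit.  Stops early when the
    cost reaches ``E_tol`` or no improving step exists.  A non-finite cost
    raises :class:`ConvergenceError` carrying the step history.
    """
    p0 = np.asarray(p0, dtype=float)
    r0 = residual_fn(p0)
    state = LMState(p=p0.copy(), lam=config.lambda0, chi2=chi_square(r0, np.zeros_like(r0), config.sigma))
    if not np.isfinite(state.chi2):
        raise ConvergenceError("initial cost is non-finite", state.history)

    def evaluate(p):
        r = residual_fn(p)
        return float(np.sum((r / config.sigma) ** 2))

    for _ in range(config.epochs):
        if state.chi2 <= config.E_tol:
            break
        J = jac_fn(state.p)
        r = residual_fn(state.p)
        accepted = False
        for _ in range(config.max_tries):
            state = lm_step(state, J, r, config, evaluate)
            if state.history and state.history[-1][2]:
                accepted = True
                break
            if state.lam > config.lambda_max:
                break
        if not np.isfinite(state.chi2):
            raise ConvergenceError("cost diverged", state.history)
        if not accepted:
            break  # converged: no strictly improving step at any damping
    return state


def train(
    params: RNNParams,
    sequences: np.ndarray,
    targets: np.ndarray,
    config: LMConfig = LMConfig(),
    obs: str = "last",
) -> tuple[RNNParams, LMState]:
    """Train a network on (sequence, target) pairs with full-batch LM.

    Parameters
    ----------
    sequences : ndarray, (n, T, n_input)
    targets : ndarray
        Desired outputs in [-1, +1]; shape (n,) for ``obs='last'`` or
        (n, T) for ``obs='all'``.

    Returns
    -------
    (RNNParams, LMState)
        Best-so-far parameters (accepted-step costs are monotone
        non-increasing) and the final optimizer state.
    """
    X = _check_sequences(sequences, params)
    y = np.asarray(targets, dtype=float).ravel()
    if y.size == 0:
        raise PreconditionError("empty dataset")
    if np.any(np.abs(y) > 1):
        raise PreconditionError("targets must lie in [-1, +1]")
    expected = X.shape[0] * (X.shape[1] if obs == "all" else 1)
    if y.size != expected:
        raise SchemaError(f"{y.size} targets for {expected} observations")

    def residual_fn(p):
        pr = params.with_flat(p)
        _, Y = _forward_batch(pr, X)
        yhat = Y[:, :, 0].ravel() if obs == "all" else Y[:, -1, 0]
        return y - yhat

    def jac_fn(p):
        J, _ = jacobian(params.with_flat(p), X, obs=obs)
        return J

    state = lm_fit(params.flatten(), residual_fn, jac_fn, config)
    return params.with_flat(state.p), state


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_params(params: RNNParams, path) -> None:
    """Persist weights plus structure settings; round-trips bit-exactly."""
    np.savez(
        path,
        W_ax=params.W_ax, W_aa=params.W_aa, W_ya=params.W_ya,
        b_a=params.b_a, b_y=params.b_y,
        delay_scale=params.delay_scale,
        output_from=np.array(params.output_from),
    )


def load_params(path) -> RNNParams:
    with np.load(path) as z:
        return RNNParams(
            W_ax=z["W_ax"], W_aa=z["W_aa"], W_ya=z["W_ya"],
            b_a=z["b_a"], b_y=z["b_y"],
            delay_scale=float(z["delay_scale"]),
            output_from=str(z["output_from"]),
        )
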