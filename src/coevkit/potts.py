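"""Pseudolikelihood Potts model fitting and coupling scores.

The co-evolutionary signal in an alignment is modelled by a global Potts
model (a pairwise Markov random field over columns with 21 states per
position): single-site fields ``h_i(a)`` and pairwise couplings
``J_ij(a, b)``. The intractable likelihood is replaced by the
pseudolikelihood — the product over columns of the conditional
probability of the observed state given all other columns — with L2
penalties on fields and couplings. Couplings are converted to a
residue-pair score by the Frobenius norm of the 20x20 amino-acid
sub-block, followed by the average-product correction (APC).

The API follows the model/results convention: build a
:class:`PottsPseudolikelihood` from an :class:`~coevkit.msa.Alignment`,
call :meth:`~PottsPseudolikelihood.fit`, and read couplings and scores
off the returned :class:`PottsResults`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .alphabet import ALPHABET, N_STATES
from .msa import Alignment

__all__ = [
    "PottsModel",
    "ScoreMatrix",
    "PottsPseudolikelihood",
    "PottsResults",
    "plm_objective",
    "fit_plm",
    "coupling_score_matrix",
    "sequence_weights",
    "write_score_table",
    "read_score_table",
]


class NumericalFailure(RuntimeError):
    """The objective became non-finite during optimization."""


@dataclass(frozen=True)
class PottsModel:
    """Fields and couplings of a fitted (or constructed) Potts model.

    ``couplings`` is the full (L, L, 21, 21) tensor, symmetric under
    (i, a, j, b) <-> (j, b, i, a), with identically zero (i, i) blocks.
    """

    fields: np.ndarray
    couplings: np.ndarray
    alphabet: str = ALPHABET
    reg_fields: float = 0.0
    reg_couplings: float = 0.0

    def __post_init__(self):
        h = np.asarray(self.fields, dtype=float)
        J = np.asarray(self.couplings, dtype=float)
        q = len(self.alphabet)
        L = h.shape[0]
        if h.shape != (L, q) or J.shape != (L, L, q, q):
            raise ValueError(f"inconsistent shapes: fields {h.shape}, couplings {J.shape}")
        if not (np.isfinite(h).all() and np.isfinite(J).all()):
            raise ValueError("non-finite model entries")
        if not np.allclose(J, J.transpose(1, 0, 3, 2), atol=1e-10):
            raise ValueError("couplings must be symmetric under (i,a,j,b) <-> (j,b,i,a)")
        if np.abs(J[np.arange(L), np.arange(L)]).max(initial=0.0) > 1e-12:
            raise ValueError("diagonal coupling blocks must be zero")
        object.__setattr__(self, "fields", h)
        object.__setattr__(self, "couplings", J)

    @property
    def length(self) -> int:
        return self.fields.shape[0]

    @classmethod
    def zeros(cls, length: int, **kw) -> "PottsModel":
        q = N_STATES
        return cls(np.zeros((length, q)), np.zeros((length, length, q, q)), **kw)

    def save(self, path) -> None:
        """Save to a compressed ``.npz`` container."""
        np.savez_compressed(
            path, fields=self.fields, couplings=self.couplings,
            alphabet=np.array(self.alphabet),
            reg=np.array([self.reg_fields, self.reg_couplings]),
        )

    @classmethod
    def load(cls, path) -> "PottsModel":
        z = np.load(path, allow_pickle=False)
        return cls(z["fields"], z["couplings"], str(z["alphabet"]),
                   float(z["reg"][0]), float(z["reg"][1]))


@dataclass(frozen=True)
class ScoreMatrix:
    """Symmetric non-negative residue-pair coupling scores, zero diagonal."""

    scores: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=float)
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise ValueError("score matrix must be square")
        if not np.allclose(s, s.T):
            raise ValueError("score matrix must be symmetric")
        if s.min(initial=0.0) < 0 or np.abs(np.diag(s)).max(initial=0.0) > 0:
            raise ValueError("scores must be non-negative with zero diagonal")
        object.__setattr__(self, "scores", s)

    @property
    def length(self) -> int:
        return self.scores.shape[0]


# ---------------------------------------------------------------------------
# internal parametrization: fields + one (q, q) block per pair i < j

def _pair_indices(L: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(L, k=1)


def _model_to_params(model: PottsModel) -> np.ndarray:
    iu, ju = _pair_indices(model.length)
    return np.concatenate([model.fields.ravel(),
                           model.couplings[iu, ju].ravel()])


def _params_to_model(params: np.ndarray, L: int, reg_f: float, reg_J: float) -> PottsModel:
    q = N_STATES
    h = params[: L * q].reshape(L, q)
    Jp = params[L * q:].reshape(-1, q, q)
    J = np.zeros((L, L, q, q))
    iu, ju = _pair_indices(L)
    J[iu, ju] = Jp
    J[ju, iu] = Jp.transpose(0, 2, 1)
    return PottsModel(h, J, reg_fields=reg_f, reg_couplings=reg_J)


def _objective(params: np.ndarray, Xf: np.ndarray, xidx: np.ndarray,
               w: np.ndarray, L: int, reg_f: float, reg_J: float
               ) -> tuple[float, np.ndarray]:
    """Weighted negative log-pseudolikelihood + L2 penalties, with gradient."""
    q = N_STATES
    N = Xf.shape[0]
    h = params[: L * q].reshape(L, q)
    Jp = params[L * q:].reshape(-1, q, q)
    iu, ju = _pair_indices(L)

    # (i*q+a, j*q+b) coupling matrix; symmetric, zero diagonal blocks
    A = np.zeros((L, q, L, q))
    A[iu, :, ju, :] = Jp
    A[ju, :, iu, :] = Jp.transpose(0, 2, 1)
    Aflat = A.reshape(L * q, L * q)

    logits = (Xf @ Aflat).reshape(N, L, q) + h[None, :, :]
    lse = logsumexp(logits, axis=2)
    obs = np.take_along_axis(logits, xidx[:, :, None], axis=2)[:, :, 0]
    nll = float(np.dot(w, (lse - obs).sum(axis=1)))

    P = np.exp(logits - lse[:, :, None])
    R = (P - Xf.reshape(N, L, q)) * w[:, None, None]
    grad_h = R.sum(axis=0)
    G = (R.reshape(N, L * q).T @ Xf).reshape(L, q, L, q)
    # J_ij enters both column i's and column j's conditionals
    grad_Jp = G[iu, :, ju, :] + G[ju, :, iu, :].transpose(0, 2, 1)

    value = nll + reg_f * float(np.sum(h * h)) + reg_J * float(np.sum(Jp * Jp))
    grad_h = grad_h + 2.0 * reg_f * h
    grad_Jp = grad_Jp + 2.0 * reg_J * Jp
    return value, np.concatenate([grad_h.ravel(), grad_Jp.ravel()])


def sequence_weights(aln: Alignment, identity: float = 0.8) -> np.ndarray:
    """Down-weight redundant rows: w = 1 / #rows within ``identity``.

    Identity here is the plain fraction of identical alignment positions
    (gaps included), the convention used by CCMpred-style fitting.
    """
    m = aln.matrix
    n = m.shape[0]
    w = np.empty(n)
    thr = identity * m.shape[1]
    for r in range(n):
        w[r] = 1.0 / max(int(((m == m[r]).sum(axis=1) >= thr).sum()), 1)
    return w


def plm_objective(model: PottsModel, aln: Alignment, weights: np.ndarray
                  ) -> tuple[float, PottsModel]:
    """Evaluate the penalized pseudolikelihood objective and its gradient.

    The gradient is returned as a :class:`PottsModel`-shaped object whose
    coupling block (i, j) holds the derivative with respect to the single
    shared parameter ``J_ij(a, b) = J_ji(b, a)`` (i.e. it accumulates the
    contributions of both conditionals).
    """
    if model.length != aln.length:
        raise ValueError("model length does not match alignment length")
    w = np.asarray(weights, dtype=float)
    if w.shape != (aln.depth,) or (w <= 0).any():
        raise ValueError("weights must be positive, one per alignment row")
    Xf = _one_hot(aln)
    params = _model_to_params(model)
    value, grad = _objective(params, Xf, aln.matrix.astype(np.int64),
                             w, aln.length, model.reg_fields, model.reg_couplings)
    return value, _params_to_model(grad, aln.length, model.reg_fields,
                                   model.reg_couplings)


def _one_hot(aln: Alignment) -> np.ndarray:
    N, L = aln.matrix.shape
    Xf = np.zeros((N, L * N_STATES))
    Xf[np.arange(N)[:, None], np.arange(L)[None, :] * N_STATES + aln.matrix] = 1.0
    return Xf


class PottsPseudolikelihood:
    """Potts model of an alignment, fitted by penalized pseudolikelihood.

    Parameters
    ----------
    alignment : Alignment
        Filtered alignment (gap columns and redundant rows removed).
    reg_fields : float
        L2 strength on fields (default 0.01).
    reg_couplings : float, optional
        Aggregate L2 strength on coupling blocks; defaults to
        ``0.2 * (L - 1)``, the CCMpred-lineage scaling.
    weights : array, optional
        Explicit per-row weights; overrides ``seq_weighting``.
    seq_weighting : bool
        Down-weight rows by the number of neighbours within 80%
        identity (default on).
    """

    def __init__(self, alignment: Alignment, reg_fields: float = 0.01,
                 reg_couplings: float | None = None,
                 weights: np.ndarray | None = None,
                 seq_weighting: bool = True):
        self.alignment = alignment
        L = alignment.length
        self.reg_fields = float(reg_fields)
        self.reg_couplings = float(0.2 * (L - 1) if reg_couplings is None
                                   else reg_couplings)
        if weights is not None:
            w = np.asarray(weights, dtype=float)
            if w.shape != (alignment.depth,) or (w <= 0).any():
                raise ValueError("weights must be positive, one per row")
            self.weights = w
        elif seq_weighting:
            self.weights = sequence_weights(alignment)
        else:
            self.weights = np.ones(alignment.depth)
        self._Xf = _one_hot(alignment)
        self._xidx = alignment.matrix.astype(np.int64)

    def objective(self, params: np.ndarray) -> tuple[float, np.ndarray]:
        return _objective(params, self._Xf, self._xidx, self.weights,
                          self.alignment.length, self.reg_fields,
                          self.reg_couplings)

    def fit(self, max_iter: int = 100, tol: float = 1e-4,
            keep_history: bool = False) -> "PottsResults":
        """Minimize by L-BFGS from zero initialization (deterministic).

        ``keep_history`` records the objective at every accepted iterate
        (at the cost of one extra evaluation per iteration).
        """
        if self.alignment.depth < 2:
            import warnings
            warnings.warn("fitting a Potts model to a single sequence: "
                          "no covariation signal is available")
        L = self.alignment.length
        n_eval = [0]

        def f(p):
            n_eval[0] += 1
            v, g = self.objective(p)
            if not np.isfinite(v):
                raise NumericalFailure(
                    f"objective became non-finite at evaluation {n_eval[0]}")
            return v, g

        x0 = np.zeros(L * N_STATES + (L * (L - 1) // 2) * N_STATES ** 2)
        history: list[float] = [self.objective(x0)[0]] if keep_history else []
        callback = ((lambda xk: history.append(self.objective(xk)[0]))
                    if keep_history else None)
        res = minimize(f, x0, jac=True, method="L-BFGS-B", callback=callback,
                       options={"maxiter": max_iter, "gtol": tol,
                                "maxfun": max(3 * max_iter, 200)})
        model = _params_to_model(res.x, L, self.reg_fields, self.reg_couplings)
        return PottsResults(self, model, bool(res.success), int(res.nit),
                            float(res.fun), float(np.abs(res.jac).max()),
                            tuple(history))


@dataclass
class PottsResults:
    """Fit results: parameters, convergence diagnostics, derived scores."""

    model: PottsPseudolikelihood
    params: PottsModel
    converged: bool
    n_iter: int
    objective: float
    grad_norm: float
    history: tuple[float, ...] = ()

    def score_matrix(self, apc: bool = True) -> ScoreMatrix:
        return coupling_score_matrix(self.params, apc=apc)

    def summary(self) -> str:
        a = self.model.alignment
        lines = [
            "Potts pseudolikelihood fit",
            "=" * 40,
            f"columns (len):        {a.length}",
            f"rows (seq):           {a.depth}",
            f"effective rows:       {self.model.weights.sum():.1f}",
            f"reg (fields, pairs):  {self.model.reg_fields:g}, "
            f"{self.model.reg_couplings:g}",
            f"iterations:           {self.n_iter}",
            f"converged:            {self.converged}",
            f"objective:            {self.objective:.4f}",
            f"max |gradient|:       {self.grad_norm:.3e}",
        ]
        return "\n".join(lines)


def fit_plm(aln: Alignment, reg_fields: float = 0.01,
            reg_couplings: float | None = None, max_iter: int = 100,
            tol: float = 1e-4, seq_weighting: bool = True) -> PottsModel:
    """Convenience wrapper: fit and return the :class:`PottsModel`."""
    return PottsPseudolikelihood(
        aln, reg_fields=reg_fields, reg_couplings=reg_couplings,
        seq_weighting=seq_weighting).fit(max_iter=max_iter, tol=tol).params


def apc_correct(S: np.ndarray) -> np.ndarray:
    """Average-product correction of a symmetric score matrix.

    Subtracts ``row_mean * col_mean / grand_mean``; exact annihilation
    of rank-one (separable) background, the phylogenetic/entropic bias
    APC exists to suppress. The input diagonal participates in the
    means; callers with zero diagonals get the standard ranking.
    """
    total = S.sum()
    if total <= 0:
        return S.copy()
    return S - np.outer(S.sum(axis=1), S.sum(axis=1)) / total


def coupling_score_matrix(model: PottsModel, apc: bool = True) -> ScoreMatrix:
    """Frobenius-norm coupling scores with optional APC.

    score(i, j) is the Frobenius norm of the 20x20 amino-acid sub-block
    of coupling (i, j) (the gap state is excluded). With ``apc`` the
    average-product correction is subtracted and negatives are clipped
    to zero.
    """
    sub = model.couplings[:, :, :20, :20]
    S = np.sqrt((sub ** 2).sum(axis=(2, 3)))
    np.fill_diagonal(S, 0.0)
    if apc:
        S = apc_correct(S)
        np.fill_diagonal(S, 0.0)
        S = np.clip((S + S.T) / 2.0, 0.0, None)
    return ScoreMatrix(S)


def write_score_table(scores: ScoreMatrix, path) -> None:
    """Tab-separated ``i  j  raw_score`` with 1-based indices, i < j."""
    with open(path, "w") as fh:
        fh.write("i\tj\traw_score\n")
        L = scores.length
        for i in range(L):
            for j in range(i + 1, L):
                fh.write(f"{i + 1}\t{j + 1}\t{scores.scores[i, j]:.6f}\n")


def read_score_table(path, length: int | None = None) -> ScoreMatrix:
    import pandas as pd
    df = pd.read_csv(path, sep="\t")
    L = length or int(max(df["i"].max(), df["j"].max()))
    S = np.zeros((L, L))
    S[df["i"] - 1, df["j"] - 1] = df["raw_score"]
    S = S + S.T
    return ScoreMatrix(S)
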