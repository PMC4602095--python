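"""Model-ensemble convergence, central-model selection, and trimming.

The modelling engines this toolkit feeds (fragment assembly, hybridize/
recombination) return large ensembles of candidate structures. This
module answers three questions about such an ensemble:

* did the sampling converge? — mean pairwise TM-score of the top models,
  classified as converged (> 0.8), converged over substructures
  (0.5–0.8, boundaries inclusive) or not converged (< 0.5);
* which single model best represents it? — the model closest to the
  iteratively superposed mean of the lowest-energy fraction;
* which residues should be trusted? — residues are trimmed when their
  Gaussian-smoothed per-residue mean square Cα deviation exceeds
  2 Å² (mobile), when too few restraints fall near them
  (unconstrained), or when most of their restraints are violated in
  the central model (violated).

Superposition uses least-squares Kabsch fitting; the ensemble mean is
obtained by iterating superposition against the running mean structure
until it stops moving, a deterministic stand-in for maximum-likelihood
ensemble superposition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .restraints import Restraint, restraint_value
from .structure_contacts import Structure

__all__ = [
    "ModelEnsemble",
    "TrimReport",
    "kabsch_superpose",
    "tm_score",
    "pairwise_tm_matrix",
    "classify_mean_tm",
    "convergence_class",
    "select_top_fraction",
    "select_central_model",
    "superpose_to_mean",
    "trim_unreliable",
    "rmsd_over_subset",
]


@dataclass(frozen=True)
class ModelEnsemble:
    """Models sharing one residue numbering, with optional per-model scores."""

    models: tuple[Structure, ...]
    scores: tuple[float, ...] | None = None

    def __post_init__(self):
        ms = tuple(self.models)
        if not ms:
            raise ValueError("empty ensemble")
        first = ms[0].chains[0]
        for m in ms:
            c = m.chains[0]
            if len(c) != len(first) or c.res_names != first.res_names:
                raise ValueError("all models must share length and residue typing")
        object.__setattr__(self, "models", ms)
        if self.scores is not None:
            sc = tuple(float(s) for s in self.scores)
            if len(sc) != len(ms):
                raise ValueError("one score per model required")
            object.__setattr__(self, "scores", sc)

    def __len__(self) -> int:
        return len(self.models)

    @property
    def length(self) -> int:
        return len(self.models[0].chains[0])

    def ca_stack(self) -> np.ndarray:
        """(n_models, length, 3) Cα coordinates."""
        return np.stack([m.chains[0].ca for m in self.models])


def kabsch_superpose(a: np.ndarray, b: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``b`` onto ``a``.

    Returns ``(rotation, translation, rmsd)`` with
    ``b @ rotation.T + translation ~ a``; the rotation is proper
    (determinant +1), so mirror images are not superposable to zero.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] < 3:
        raise ValueError("need two equal sets of at least 3 points")
    ca_, cb_ = a.mean(axis=0), b.mean(axis=0)
    H = (b - cb_).T @ (a - ca_)
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-12 * max(S[0], 1.0):
        raise ValueError("degenerate (collinear) point set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = ca_ - cb_ @ R.T
    rmsd = float(np.sqrt(((b @ R.T + t - a) ** 2).sum(axis=1).mean()))
    return R, t, rmsd


def _tm_d0(l_ref: int) -> float:
    if l_ref > 15:
        return max(1.24 * (l_ref - 15) ** (1.0 / 3.0) - 1.8, 0.5)
    return 0.5


def tm_score(model: Structure, ref: Structure) -> float:
    """TM-score of ``model`` against ``ref`` under the identity pairing.

    Normalized by the reference length with
    ``d0 = 1.24 (L_ref - 15)^(1/3) - 1.8`` (floored at 0.5 Å) and
    maximized over iteratively refined fragment-seeded superpositions,
    as in the published algorithm. Invariant to rigid motion of either
    input; 1.0 for identical structures.
    """
    ca_m, ca_r = _common_ca(model, ref)
    n = ca_m.shape[0]
    if n < 3:
        raise ValueError("need at least 3 common residues")
    l_ref = len(ref.chains[0])
    d0 = _tm_d0(l_ref)

    def tm_of(sel: np.ndarray) -> tuple[float, np.ndarray]:
        R, t, _ = kabsch_superpose(ca_r[sel], ca_m[sel])
        moved = ca_m @ R.T + t
        d2 = ((moved - ca_r) ** 2).sum(axis=1)
        return float((1.0 / (1.0 + d2 / d0 ** 2)).sum()) / l_ref, d2

    best = 0.0
    frag_lens = sorted({n, max(n // 2, 4), max(n // 4, 4), 4})
    for fl in frag_lens:
        if fl > n:
            continue
        step = max(fl // 2, 1)
        for start in range(0, n - fl + 1, step):
            sel = np.arange(start, start + fl)
            prev: np.ndarray | None = None
            for _ in range(20):
                try:
                    score, d2 = tm_of(sel)
                except ValueError:
                    break  # collinear fragment seed
                best = max(best, score)
                # grow the aligned set: residues within a distance shell
                cut = d0
                new = np.nonzero(d2 < cut ** 2)[0]
                while new.size < 4:
                    cut += 0.5
                    new = np.nonzero(d2 < cut ** 2)[0]
                if prev is not None and np.array_equal(new, prev):
                    break
                prev, sel = sel, new
    return best


def _common_ca(model: Structure, ref: Structure) -> tuple[np.ndarray, np.ndarray]:
    cm, cr = model.chains[0], ref.chains[0]
    common = sorted(set(cm.res_ids.tolist()) & set(cr.res_ids.tolist()))
    pm = {int(r): k for k, r in enumerate(cm.res_ids)}
    pr = {int(r): k for k, r in enumerate(cr.res_ids)}
    am = np.array([cm.ca[pm[r]] for r in common])
    ar = np.array([cr.ca[pr[r]] for r in common])
    return am, ar


def pairwise_tm_matrix(models: Sequence[Structure]) -> np.ndarray:
    """Symmetric-average TM-score matrix with unit diagonal."""
    n = len(models)
    M = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            s = 0.5 * (tm_score(models[i], models[j])
                       + tm_score(models[j], models[i]))
            M[i, j] = M[j, i] = s
    return M


def classify_mean_tm(mean_tm: float) -> str:
    """Convergence label from a mean pairwise TM-score.

    Boundaries are assigned to the substructure class: exactly 0.8 or
    exactly 0.5 both read "converged over substructures".
    """
    if mean_tm > 0.8:
        return "converged"
    if mean_tm >= 0.5:
        return "substructure"
    return "not_converged"


def convergence_class(e: ModelEnsemble, top_n: int = 10
                      ) -> tuple[str, float]:
    """Classify convergence from the mean pairwise TM-score of top models.

    Returns ``(label, mean_tm)`` with label in {"converged",
    "substructure", "not_converged"}; boundaries 0.5 and 0.8 both map to
    "substructure". Top models are the lowest-scoring ``top_n`` when
    scores are present, else the first ``top_n``.
    """
    if len(e) < 2:
        raise ValueError("convergence needs at least 2 models")
    idx = (np.argsort(e.scores, kind="stable")[:top_n]
           if e.scores is not None else np.arange(min(top_n, len(e))))
    models = [e.models[i] for i in idx]
    M = pairwise_tm_matrix(models)
    iu = np.triu_indices(len(models), k=1)
    mean_tm = float(M[iu].mean())
    return classify_mean_tm(mean_tm), mean_tm


def select_top_fraction(e: ModelEnsemble, fraction: float = 0.05
                        ) -> ModelEnsemble:
    """Keep the ``ceil(fraction * N)`` lowest-score models (stable ties)."""
    if e.scores is None:
        raise ValueError("ensemble has no scores")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    k = math.ceil(fraction * len(e))
    idx = np.argsort(e.scores, kind="stable")[:k]
    idx = np.sort(idx)  # keep input order among the retained models
    return ModelEnsemble(tuple(e.models[i] for i in idx),
                         tuple(e.scores[i] for i in idx))


def superpose_to_mean(e: ModelEnsemble, tol: float = 1e-3,
                      max_iter: int = 100
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Iteratively superpose all models onto their running mean Cα structure.

    Returns ``(stack, mean)``: the superposed (n, L, 3) coordinates and
    the converged mean (L, 3). Iteration stops when the mean moves less
    than ``tol`` Å RMS.
    """
    stack = e.ca_stack()
    mean = stack[0].copy()
    for _ in range(max_iter):
        for k in range(stack.shape[0]):
            R, t, _ = kabsch_superpose(mean, stack[k])
            stack[k] = stack[k] @ R.T + t
        new_mean = stack.mean(axis=0)
        move = float(np.sqrt(((new_mean - mean) ** 2).sum(axis=1).mean()))
        mean = new_mean
        if move < tol:
            break
    return stack, mean


def select_central_model(e: ModelEnsemble) -> Structure:
    """The model with lowest Cα RMSD to the converged ensemble mean.

    Ties (e.g. all models identical) resolve to the first model.
    """
    if len(e) < 2:
        raise ValueError("need at least 2 models")
    stack, mean = superpose_to_mean(e)
    rmsds = np.sqrt(((stack - mean) ** 2).sum(axis=2).mean(axis=1))
    return e.models[int(np.argmin(rmsds))]


def _gaussian_smooth(x: np.ndarray, halfwin: int, sigma: float) -> np.ndarray:
    """Truncated-Gaussian smoothing, weights renormalized at the termini."""
    offsets = np.arange(-halfwin, halfwin + 1)
    w = np.exp(-0.5 * (offsets / sigma) ** 2)
    n = x.size
    out = np.empty(n)
    for r in range(n):
        lo, hi = max(r - halfwin, 0), min(r + halfwin, n - 1)
        ww = w[lo - r + halfwin: hi - r + halfwin + 1]
        out[r] = float((x[lo:hi + 1] * ww).sum() / ww.sum())
    return out


@dataclass(frozen=True)
class TrimReport:
    """Per-residue reliability assessment of a superposed ensemble."""

    msd_raw: np.ndarray
    msd_smooth: np.ndarray
    retained: np.ndarray            # boolean mask, True = keep
    reasons: dict[int, tuple[str, ...]]  # residue id -> flags
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (len(self.msd_raw) == len(self.msd_smooth) == len(self.retained)):
            raise ValueError("inconsistent report lengths")
        for rid, why in self.reasons.items():
            if not why:
                raise ValueError(f"trimmed residue {rid} has no reason")

    @property
    def retained_ids(self) -> list[int]:
        ids = self.metadata.get("res_ids")
        return [int(r) for r, keep in zip(ids, self.retained) if keep]


def trim_unreliable(e_top: ModelEnsemble, restraints: Sequence[Restraint],
                    msd_cut: float = 2.0, halfwin: int = 3,
                    sigma: float = 1.5, min_restraints: int = 2,
                    restraint_window: int = 4,
                    violation_frac: float = 0.5) -> TrimReport:
    """Flag mobile, unconstrained, and restraint-violating residues.

    1. Superpose all models to the converged mean; per-residue MSD is
       the mean squared Cα deviation from the mean coordinates.
    2. Smooth the MSD profile with a Gaussian (sigma 1.5 residues)
       truncated at +-``halfwin`` residues, renormalized at the termini.
    3. Residues with smoothed MSD > ``msd_cut`` (default 2 Å²) are
       flagged *mobile*.
    4. Residues with fewer than ``min_restraints`` restraints touching
       the +-``restraint_window`` window around them are flagged
       *unconstrained*; residues where more than ``violation_frac`` of
       incident restraints are violated (distance above the restraint
       cutoff in the central model) are flagged *violated*.

    The retained mask is the complement of all flags.
    """
    chain = e_top.models[0].chains[0]
    res_ids = chain.res_ids
    valid = set(int(r) for r in res_ids)
    for r in restraints:
        if r.i not in valid or r.j not in valid:
            raise ValueError(f"restraint ({r.i}, {r.j}) outside ensemble numbering")

    stack, mean = superpose_to_mean(e_top)
    msd_raw = ((stack - mean) ** 2).sum(axis=2).mean(axis=0)
    msd_smooth = _gaussian_smooth(msd_raw, halfwin, sigma)

    central = select_central_model(e_top) if len(e_top) >= 2 else e_top.models[0]
    cchain = central.chains[0]
    pos = {int(r): k for k, r in enumerate(res_ids)}

    def restraint_distance(r: Restraint) -> float:
        pi = cchain.ca[pos[r.i]] if r.atom_i == "CA" else cchain.cb[pos[r.i]]
        pj = cchain.ca[pos[r.j]] if r.atom_j == "CA" else cchain.cb[pos[r.j]]
        return float(np.linalg.norm(pi - pj))

    violated_pairs = {(r.i, r.j) for r in restraints
                      if restraint_distance(r) > r.cutoff}

    reasons: dict[int, list[str]] = {}
    retained = np.ones(len(res_ids), dtype=bool)
    for k, rid_np in enumerate(res_ids):
        rid = int(rid_np)
        flags = []
        if msd_smooth[k] > msd_cut:
            flags.append("mobile")
        near = [r for r in restraints
                if min(abs(r.i - rid), abs(r.j - rid)) <= restraint_window]
        if len(near) < min_restraints:
            flags.append("unconstrained")
        incident = [r for r in restraints if rid in (r.i, r.j)]
        if incident:
            n_viol = sum((r.i, r.j) in violated_pairs for r in incident)
            if n_viol / len(incident) > violation_frac:
                flags.append("violated")
        if flags:
            retained[k] = False
            reasons[rid] = flags
    return TrimReport(
        msd_raw, msd_smooth, retained,
        {rid: tuple(f) for rid, f in reasons.items()},
        metadata={"res_ids": res_ids.tolist(),
                  "superposition": "iterative-mean-least-squares",
                  "msd_cut": msd_cut, "halfwin": halfwin, "sigma": sigma},
    )


def rmsd_over_subset(model: Structure, ref: Structure,
                     mask: Sequence[int]) -> float:
    """Kabsch-superposed Cα RMSD restricted to the residue ids in ``mask``."""
    cm, cr = model.chains[0], ref.chains[0]
    pm = {int(r): k for k, r in enumerate(cm.res_ids)}
    pr = {int(r): k for k, r in enumerate(cr.res_ids)}
    ids = [int(r) for r in mask if int(r) in pm and int(r) in pr]
    if len(ids) < 3:
        raise ValueError("mask must cover at least 3 residues present in both")
    a = np.array([cr.ca[pr[r]] for r in ids])
    b = np.array([cm.ca[pm[r]] for r in ids])
    return kabsch_superpose(a, b)[2]
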