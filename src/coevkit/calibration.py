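"""Score normalization and calibrated contact probabilities.

Raw coupling scores are not comparable across protein families: their
scale depends on alignment depth, length and regularization. Two steps
make them comparable and probabilistic:

1. **Normalization** — the top ``ceil(3L/2)`` pairs with sequence
   separation >= 3 are rescaled affinely so their minimum is 0.5 and
   their mean is 1.0. The rescaled value is the normalized score *sco*.
2. **Calibration** — the probability that a pair is a true contact is a
   sigmoid in *sco* whose slope and midpoint depend on the alignment
   depth *seq* and length *len* through the ratio r = seq/sqrt(len),
   mixed with a separation-dependent background::

       P(contact | sco, seq, len, sep)
           = b(sep) + 0.89 (1 - b(sep))
             / (1 + exp(-0.58 r^0.50 (sco - 5.46 r^-0.53)))

   The five constants were calibrated on a large set of solved
   structures and are shipped as defaults; the background b(sep) is the
   contact frequency of residue pairs at each separation irrespective
   of score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .potts import ScoreMatrix

__all__ = [
    "ContactPredictionSet",
    "AccuracyModel",
    "DegenerateNormalizationError",
    "normalize_scores",
    "contact_probability",
    "score_probabilities",
    "fit_background",
    "zero_background",
    "write_prediction_table",
    "read_prediction_table",
]


class DegenerateNormalizationError(ValueError):
    """All selected raw scores are equal; the affine rescaling is undefined."""


@dataclass(frozen=True)
class ContactPredictionSet:
    """Top-ranked residue pairs with normalized scores and probabilities.

    ``table`` columns: ``i``, ``j`` (1-based, i < j), ``raw``, ``sco``,
    ``sep`` (= j - i), ``prob`` (NaN until :func:`score_probabilities`).
    """

    table: pd.DataFrame
    length: int
    depth: int

    def __post_init__(self):
        t = self.table
        required = ["i", "j", "raw", "sco", "sep", "prob"]
        if list(t.columns) != required:
            raise ValueError(f"prediction table must have columns {required}")
        if len(t) > math.ceil(3 * self.length / 2):
            raise ValueError("more pairs than the top-3L/2 selection allows")
        if (t["sep"] < 3).any():
            raise ValueError("all pairs must have sequence separation >= 3")

    @property
    def has_probabilities(self) -> bool:
        return bool(self.table["prob"].notna().all())


def zero_background(sep: int) -> float:
    """Background of exactly zero; the analytic-test configuration."""
    return 0.0


@dataclass(frozen=True)
class AccuracyModel:
    """The calibrated P(contact | sco, seq, len, sep) model.

    The default constants are the shipped calibration; ``background`` is
    P(contact | sep), a callable of separation returning a probability
    in [0, 1).
    """

    amplitude: float = 0.89
    slope_coef: float = 0.58
    ratio_exp: float = 0.50
    offset_coef: float = 5.46
    offset_exp: float = -0.53
    background: Callable[[int], float] = zero_background

    def __post_init__(self):
        if min(self.amplitude, self.slope_coef, self.offset_coef) <= 0:
            raise ValueError("amplitude, slope_coef and offset_coef must be positive")

    def with_background(self, background: Callable[[int], float]) -> "AccuracyModel":
        return replace(self, background=background)


def normalize_scores(raw: ScoreMatrix, depth: int = 0) -> ContactPredictionSet:
    """Select the top ceil(3L/2) pairs (sep >= 3) and rescale to min 0.5, mean 1.0.

    Selection is by raw score, descending; ties at the boundary are
    broken deterministically by (smaller i, then smaller j). The affine
    map ``a*s + b`` solves the two constraints exactly:
    ``a = 0.5 / (mean - min)``, ``b = 0.5 - a * min``. Probabilities are
    left unset until :func:`score_probabilities`.

    ``depth`` records the alignment depth (*seq*) for downstream
    calibration; it is not used by the rescaling itself.
    """
    L = raw.length
    iu, ju = np.triu_indices(L, k=3)
    n_sel = math.ceil(3 * L / 2)
    if iu.size < n_sel:
        raise ValueError(
            f"need at least {n_sel} pairs with separation >= 3; have {iu.size}")
    s = raw.scores[iu, ju]
    order = np.lexsort((ju, iu, -s))  # score desc, then i asc, then j asc
    sel = order[:n_sel]
    i, j, s = iu[sel], ju[sel], s[sel]

    smin, smean = float(s.min()), float(s.mean())
    if smean <= smin:
        raise DegenerateNormalizationError(
            "all selected raw scores are equal; cannot rescale to min 0.5, mean 1.0")
    a = 0.5 / (smean - smin)
    b = 0.5 - a * smin
    sco = a * s + b

    t = pd.DataFrame({
        "i": i + 1, "j": j + 1, "raw": s, "sco": sco, "sep": j - i,
        "prob": np.full(n_sel, np.nan),
    }).sort_values(["sco", "i", "j"], ascending=[False, True, True],
                   ignore_index=True)
    return ContactPredictionSet(t, length=L, depth=int(depth))


def contact_probability(model: AccuracyModel, sco: float, seq: int,
                        len_: int, sep: int) -> float:
    """Evaluate the calibrated contact probability; clamped to [0, 1]."""
    if seq < 1 or len_ < 1 or sep < 1:
        raise ValueError("seq, len and sep must all be >= 1")
    r = seq / math.sqrt(len_)
    b = float(model.background(sep))
    x = model.slope_coef * r ** model.ratio_exp * (
        sco - model.offset_coef * r ** model.offset_exp)
    # guard exp overflow for extremely negative normalized scores
    sig = 1.0 / (1.0 + math.exp(-x)) if x > -700 else 0.0
    p = b + model.amplitude * (1.0 - b) * sig
    return min(max(p, 0.0), 1.0)


def score_probabilities(preds: ContactPredictionSet,
                        model: AccuracyModel) -> ContactPredictionSet:
    """Fill the probability column of a prediction set (idempotent)."""
    if preds.depth < 1:
        raise ValueError("prediction set carries no alignment depth (seq); "
                         "pass depth= to normalize_scores")
    t = preds.table.copy()
    t["prob"] = [
        contact_probability(model, row.sco, preds.depth, preds.length,
                            int(row.sep))
        for row in t.itertuples()
    ]
    return ContactPredictionSet(t, preds.length, preds.depth)


def fit_background(contact_maps: Iterable) -> Callable[[int], float]:
    """Empirical P(contact | sep), pooled over maps, monotone-smoothed.

    For each separation the fraction of residue pairs in contact is
    pooled over the input maps; isotonic regression enforces a
    non-increasing trend (contact frequency decays with separation);
    beyond the largest observed separation the last value is extended.
    """
    maps = list(contact_maps)
    if not maps:
        raise ValueError("at least one contact map is required")
    max_sep = max(m.length - 1 for m in maps)
    hits = np.zeros(max_sep + 1)
    tot = np.zeros(max_sep + 1)
    for m in maps:
        for sep in range(1, m.length):
            tot[sep] += m.length - sep
        for (i, j) in m.contacts:
            hits[abs(j - i)] += 1
    seps = np.nonzero(tot)[0]
    frac = hits[seps] / tot[seps]

    if frac.sum() == 0:
        smooth = np.zeros_like(frac)
    else:
        from sklearn.isotonic import IsotonicRegression
        smooth = IsotonicRegression(increasing=False,
                                    y_min=0.0, y_max=1.0 - 1e-9
                                    ).fit_transform(seps, frac)
    lookup = dict(zip(seps.tolist(), smooth.tolist()))
    last_sep = int(seps.max())

    def background(sep: int) -> float:
        if sep < 1:
            raise ValueError("sep must be >= 1")
        return float(lookup.get(min(sep, last_sep), lookup[last_sep]))

    return background


def write_prediction_table(preds: ContactPredictionSet, path) -> None:
    """Tab-separated ``i  j  raw  sco  sep  prob`` with 1-based indices."""
    t = preds.table.copy()
    with open(path, "w") as fh:
        fh.write(f"# len={preds.length} seq={preds.depth}\n")
        t.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def read_prediction_table(path) -> ContactPredictionSet:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError("missing '# len=.. seq=..' header line")
        meta = dict(kv.split("=") for kv in header[1:].split())
        t = pd.read_csv(fh, sep="\t")
    return ContactPredictionSet(t, int(meta["len"]), int(meta["seq"]))
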