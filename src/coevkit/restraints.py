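"""Sigmoidal distance restraints from contact predictions.

Each predicted pair becomes a bounded attractive well between the two
Cβ atoms (Cα for glycine)::

    restraint(d) = weight * (sigmoid(slope * (d - cutoff)) + intercept)

with the default intercept of -1 this is -weight at short range, rises
through -weight/2 at d = cutoff, and vanishes at long range, so a
violated restraint costs a bounded amount rather than diverging. The
weight is three times the normalized coupling score; since normalized
scores average 1.0 over the selected set, the restraint set's total
dynamic range is about 3 energy units per predicted pair, commensurate
with a typical all-atom energy function. Cutoffs and slopes are
amino-acid-pair specific in principle; the shipped default is uniform
(8.0 Å, 2.0 Å⁻¹).

Serialization supports a Rosetta-style constraint-file dialect
(``AtomPair ... SCALARWEIGHTEDFUNC <w> SIGMOID <cutoff> <slope>``) and a
plain TSV dialect, optionally staged into cumulative files by sequence
separation (restraints for residues close along the chain first, then
increasingly separated ones).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .calibration import ContactPredictionSet
from .structure_contacts import CutoffTable

__all__ = [
    "Restraint",
    "RestraintParams",
    "WEIGHT_FACTOR",
    "build_restraints",
    "restraint_value",
    "write_constraints",
    "read_constraints",
]

#: Normalized score -> restraint weight multiplier.
WEIGHT_FACTOR = 3.0

DEFAULT_STAGES: tuple[float, ...] = (12, 23, math.inf)


@dataclass(frozen=True)
class Restraint:
    """One sigmoidal Cβ–Cβ (Cα for glycine) distance restraint."""

    i: int
    j: int
    atom_i: str
    atom_j: str
    weight: float
    cutoff: float
    slope: float
    intercept: float = -1.0

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError("a restraint needs two distinct residues")
        if self.weight <= 0 or self.cutoff <= 0 or self.slope <= 0:
            raise ValueError("weight, cutoff and slope must be positive")

    @property
    def sep(self) -> int:
        return abs(self.j - self.i)


class RestraintParams:
    """Per-amino-acid-pair cutoff (Å) and slope (Å⁻¹) lookup."""

    def __init__(self, cutoffs: CutoffTable | float = 8.0,
                 slope: float = 2.0,
                 pair_slopes: dict[tuple[str, str], float] | None = None):
        self.cutoffs = (cutoffs if isinstance(cutoffs, CutoffTable)
                        else CutoffTable(float(cutoffs)))
        if slope <= 0:
            raise ValueError("slope must be positive")
        self.slope = float(slope)
        self.pair_slopes = {tuple(sorted(k)): float(v)
                            for k, v in (pair_slopes or {}).items()}

    def cutoff(self, aa1: str, aa2: str) -> float:
        return self.cutoffs(aa1, aa2)

    def slope_for(self, aa1: str, aa2: str) -> float:
        return self.pair_slopes.get(tuple(sorted((aa1, aa2))), self.slope)


def build_restraints(preds: ContactPredictionSet, sequence: str,
                     params: RestraintParams | None = None,
                     intercept: float = -1.0) -> list[Restraint]:
    """One restraint per predicted pair; weight = 3 * sco.

    ``sequence`` supplies amino-acid types (1-based indexing of the
    prediction set); glycine positions restrain Cα instead of Cβ.
    """
    params = params or RestraintParams()
    out = []
    for row in preds.table.itertuples():
        i, j = int(row.i), int(row.j)
        if i > len(sequence) or j > len(sequence):
            raise ValueError(
                f"pair ({i}, {j}) beyond sequence of length {len(sequence)}")
        aa_i, aa_j = sequence[i - 1], sequence[j - 1]
        out.append(Restraint(
            i=i, j=j,
            atom_i="CA" if aa_i == "G" else "CB",
            atom_j="CA" if aa_j == "G" else "CB",
            weight=WEIGHT_FACTOR * float(row.sco),
            cutoff=params.cutoff(aa_i, aa_j),
            slope=params.slope_for(aa_i, aa_j),
            intercept=intercept,
        ))
    return out


def restraint_value(r: Restraint, d: float) -> float:
    """Energy of one restraint at Cβ–Cβ distance ``d`` (Å).

    Monotone non-decreasing in d: -weight (satisfied, with the default
    intercept) far below the cutoff, 0 far above it, -weight/2 at the
    cutoff itself.
    """
    if d < 0:
        raise ValueError("distance must be non-negative")
    x = r.slope * (d - r.cutoff)
    sig = 1.0 / (1.0 + math.exp(-x)) if x > -700 else 0.0
    return r.weight * (sig + r.intercept)


def total_restraint_score(restraints: Sequence[Restraint], structure) -> float:
    """Sum of restraint energies evaluated on a single-chain structure."""
    import numpy as np
    chain = structure.chains[0]
    pos = {int(rid): k for k, rid in enumerate(chain.res_ids)}
    total = 0.0
    for r in restraints:
        if r.i in pos and r.j in pos:
            pi = chain.ca[pos[r.i]] if r.atom_i == "CA" else chain.cb[pos[r.i]]
            pj = chain.ca[pos[r.j]] if r.atom_j == "CA" else chain.cb[pos[r.j]]
            total += restraint_value(r, float(np.linalg.norm(pi - pj)))
    return total


def _rosetta_line(r: Restraint) -> str:
    return (f"AtomPair {r.atom_i} {r.i} {r.atom_j} {r.j} "
            f"SCALARWEIGHTEDFUNC {r.weight:.6f} "
            f"SIGMOID {r.cutoff:.6f} {r.slope:.6f}")


def write_constraints(restraints: Sequence[Restraint], path,
                      dialect: str = "rosetta_sigmoid",
                      stages: Sequence[float] | None = None) -> list[Path]:
    """Serialize restraints; returns the list of files written.

    ``rosetta_sigmoid`` emits one ``AtomPair`` line per restraint with
    fixed 6-decimal formatting; ``tsv`` emits a header plus one row with
    all fields. With ``stages`` (sequence-separation thresholds), one
    cumulative file per threshold is written (suffix ``.sep<th>``): a
    restraint appears in every file whose threshold is >= its separation.
    """
    if not restraints:
        raise ValueError("no restraints to write")
    if dialect not in ("rosetta_sigmoid", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)

    def emit(rs: Sequence[Restraint], p: Path) -> None:
        with open(p, "w") as fh:
            if dialect == "tsv":
                fh.write("i\tj\tatom_i\tatom_j\tweight\tcutoff\tslope\tintercept\n")
                for r in rs:
                    fh.write(f"{r.i}\t{r.j}\t{r.atom_i}\t{r.atom_j}\t"
                             f"{r.weight:.6f}\t{r.cutoff:.6f}\t{r.slope:.6f}\t"
                             f"{r.intercept:.6f}\n")
            else:
                for r in rs:
                    fh.write(_rosetta_line(r) + "\n")

    if stages is None:
        emit(restraints, path)
        return [path]
    files = []
    for th in stages:
        tag = "all" if math.isinf(th) else str(int(th))
        p = path.with_name(path.name + f".sep{tag}")
        emit([r for r in restraints if r.sep <= th], p)
        files.append(p)
    return files


def read_constraints(path, dialect: str = "rosetta_sigmoid",
                     intercept: float = -1.0) -> list[Restraint]:
    """Parse a constraint file written by :func:`write_constraints`."""
    out = []
    with open(path) as fh:
        if dialect == "tsv":
            header = fh.readline()
            for line in fh:
                i, j, ai, aj, w, c, s, b = line.split("\t")
                out.append(Restraint(int(i), int(j), ai, aj, float(w),
                                     float(c), float(s), float(b)))
        elif dialect == "rosetta_sigmoid":
            for line in fh:
                tok = line.split()
                if not tok:
                    continue
                if tok[0] != "AtomPair" or tok[5] != "SCALARWEIGHTEDFUNC" \
                        or tok[7] != "SIGMOID":
                    raise ValueError(f"unrecognized constraint line: {line!r}")
                out.append(Restraint(int(tok[2]), int(tok[4]), tok[1], tok[3],
                                     float(tok[6]), float(tok[8]),
                                     float(tok[9]), intercept))
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    return out
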