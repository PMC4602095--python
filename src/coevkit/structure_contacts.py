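"""Structures, contact maps, and the Rc prediction-vs-model fit metric.

A contact is a residue pair whose Cβ–Cβ distance (Cα for glycine) falls
below a cutoff; by default a uniform 8.0 Å is used, with a hook for an
amino-acid-pair-specific table. The Rc metric measures how well a
structural model satisfies a set of calibrated contact predictions: the
observed total normalized score of satisfied predicted pairs, divided by
the expected total ``sum(sco * P)`` if the model were native. Native
structures score roughly 0.7–1.2; randomly paired prediction/structure
combinations score roughly 0–0.3, so 0.7 serves as a practical cutoff
for "consistent with the predictions".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

from .alphabet import THREE_TO_ONE, ONE_TO_THREE
from .calibration import ContactPredictionSet

__all__ = [
    "Chain",
    "Structure",
    "ContactMap",
    "CutoffTable",
    "read_structure",
    "write_structure",
    "contact_map",
    "rc_score",
    "RcReport",
    "top_contact_precision",
]


@dataclass(frozen=True)
class Chain:
    """One chain: residue ids, one-letter types, Cα and Cβ coordinates (Å)."""

    chain_id: str
    res_ids: np.ndarray  # strictly increasing ints
    res_names: str       # one-letter codes, same order
    ca: np.ndarray       # (n, 3)
    cb: np.ndarray       # (n, 3); equals ca for glycine

    def __post_init__(self):
        r = np.asarray(self.res_ids, dtype=int)
        ca = np.asarray(self.ca, dtype=float)
        cb = np.asarray(self.cb, dtype=float)
        if (np.diff(r) <= 0).any():
            raise ValueError(f"chain {self.chain_id}: residue ids must be strictly increasing")
        if not (np.isfinite(ca).all() and np.isfinite(cb).all()):
            raise ValueError("non-finite coordinates")
        if not (len(r) == len(self.res_names) == ca.shape[0] == cb.shape[0]):
            raise ValueError("inconsistent chain field lengths")
        object.__setattr__(self, "res_ids", r)
        object.__setattr__(self, "ca", ca)
        object.__setattr__(self, "cb", cb)

    def __len__(self) -> int:
        return len(self.res_ids)


@dataclass(frozen=True)
class Structure:
    """An ordered list of chains; ``length`` is the largest residue id span."""

    chains: tuple[Chain, ...]

    def __post_init__(self):
        if not self.chains:
            raise ValueError("a structure needs at least one chain")
        object.__setattr__(self, "chains", tuple(self.chains))

    @property
    def length(self) -> int:
        return int(max(c.res_ids.max() for c in self.chains))

    @property
    def residue_ids(self) -> set[int]:
        out: set[int] = set()
        for c in self.chains:
            out.update(c.res_ids.tolist())
        return out

    def sequence(self) -> str:
        """One-letter sequence of the first chain."""
        return self.chains[0].res_names

    @classmethod
    def single_chain(cls, sequence: str, ca: np.ndarray, cb: np.ndarray,
                     chain_id: str = "A", res_ids: np.ndarray | None = None
                     ) -> "Structure":
        if res_ids is None:
            res_ids = np.arange(1, len(sequence) + 1)
        return cls((Chain(chain_id, res_ids, sequence, ca, cb),))


@dataclass(frozen=True)
class ContactMap:
    """Boolean contact relation: unordered residue-id pairs plus the rule used."""

    length: int
    contacts: frozenset[tuple[int, int]]
    definition: str = "CB-CB < 8.0 A"

    def __post_init__(self):
        pairs = frozenset(tuple(sorted(p)) for p in self.contacts)
        for i, j in pairs:
            if i == j:
                raise ValueError("self-contacts are not allowed")
            if not (1 <= i <= self.length and 1 <= j <= self.length):
                raise ValueError(f"pair ({i}, {j}) outside [1, {self.length}]")
        object.__setattr__(self, "contacts", pairs)

    def __contains__(self, pair: tuple[int, int]) -> bool:
        return tuple(sorted(pair)) in self.contacts

    def density(self, min_sep: int = 6) -> float:
        """Fraction of sep >= min_sep pairs that are contacts."""
        n_pairs = sum(1 for (i, j) in self.contacts if abs(j - i) >= min_sep)
        L = self.length
        tot = (L - min_sep) * (L - min_sep + 1) // 2
        return n_pairs / tot if tot else 0.0


class CutoffTable:
    """Per-amino-acid-pair Cβ–Cβ distance cutoffs (Å), with a uniform default.

    The authors' pair-specific table lives in cited prior work; the
    uniform 8.0 Å default is a documented approximation. Keys of
    ``pair_values`` are unordered one-letter pairs, e.g. ``("A", "L")``.
    """

    def __init__(self, uniform: float = 8.0,
                 pair_values: dict[tuple[str, str], float] | None = None):
        if uniform <= 0:
            raise ValueError("cutoffs must be positive")
        self.uniform = float(uniform)
        self.pair_values = {tuple(sorted(k)): float(v)
                            for k, v in (pair_values or {}).items()}
        if any(v <= 0 for v in self.pair_values.values()):
            raise ValueError("cutoffs must be positive")

    def __call__(self, aa1: str, aa2: str) -> float:
        return self.pair_values.get(tuple(sorted((aa1, aa2))), self.uniform)


DEFAULT_CUTOFFS = CutoffTable(8.0)


def _ideal_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Place Cβ from backbone N, Cα, C by ideal tetrahedral geometry."""
    b = ca - n
    cdir = c - ca
    cross = np.cross(b, cdir)
    # standard virtual-CB construction (1.522 A bond)
    u = -0.58273431 * cross + 0.56802827 * b - 0.54067466 * cdir
    return ca + 1.522 * u / np.linalg.norm(u)


def read_structure(path, model: int = 1) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    The first model of multi-model files is used by default; alternate
    locations are resolved to the highest occupancy; a missing Cβ for a
    non-glycine residue is reconstructed from backbone geometry with a
    warning. Raises ``ValueError`` when no usable ATOM records exist.
    """
    pdb = pdbio.PDBFile.read(str(path))
    atoms = pdbio.get_structure(pdb, model=model, altloc="occupancy")
    atoms = atoms[struc.filter_amino_acids(atoms)]
    if atoms.array_length() == 0:
        raise ValueError(f"no amino-acid ATOM records in {path}")

    chains: list[Chain] = []
    for cid in np.unique(atoms.chain_id):
        sub = atoms[atoms.chain_id == cid]
        res_ids, names, cas, cbs = [], [], [], []
        for rid in np.unique(sub.res_id):
            res = sub[sub.res_id == rid]
            rname = res.res_name[0]
            one = THREE_TO_ONE.get(rname)
            if one is None:
                continue
            ca_sel = res[res.atom_name == "CA"]
            if ca_sel.array_length() == 0:
                continue
            ca = ca_sel.coord[0]
            if one == "G":
                cb = ca
            else:
                cb_sel = res[res.atom_name == "CB"]
                if cb_sel.array_length() > 0:
                    cb = cb_sel.coord[0]
                else:
                    nn = res[res.atom_name == "N"]
                    cc = res[res.atom_name == "C"]
                    if nn.array_length() and cc.array_length():
                        warnings.warn(
                            f"residue {rname} {int(rid)} chain {cid}: missing CB "
                            "reconstructed from backbone geometry")
                        cb = _ideal_cb(nn.coord[0], ca, cc.coord[0])
                    else:
                        warnings.warn(
                            f"residue {rname} {int(rid)} chain {cid}: missing CB "
                            "and incomplete backbone; using CA")
                        cb = ca
            res_ids.append(int(rid))
            names.append(one)
            cas.append(ca)
            cbs.append(cb)
        if res_ids:
            chains.append(Chain(str(cid), np.array(res_ids), "".join(names),
                                np.array(cas, dtype=float),
                                np.array(cbs, dtype=float)))
    if not chains:
        raise ValueError(f"no parseable residues in {path}")
    return Structure(tuple(chains))


def write_structure(s: Structure, path) -> None:
    """Write CA/CB coordinates as a minimal PDB file."""
    n_atoms = sum(2 * len(c) - c.res_names.count("G") for c in s.chains)
    arr = struc.AtomArray(n_atoms)
    k = 0
    for c in s.chains:
        for idx in range(len(c)):
            one = c.res_names[idx]
            entries = [("CA", "C", c.ca[idx])]
            if one != "G":
                entries.append(("CB", "C", c.cb[idx]))
            for name, elem, coord in entries:
                arr.coord[k] = coord
                arr.chain_id[k] = c.chain_id
                arr.res_id[k] = int(c.res_ids[idx])
                arr.res_name[k] = ONE_TO_THREE[one]
                arr.atom_name[k] = name
                arr.element[k] = elem
                k += 1
    pdb = pdbio.PDBFile()
    pdbio.set_structure(pdb, arr)
    pdb.write(str(path))


def contact_map(s: Structure, cutoffs: CutoffTable | float = DEFAULT_CUTOFFS,
                min_sep: int = 0, cross_chain: bool = False) -> ContactMap:
    """Derive the boolean contact relation from Cβ–Cβ distances.

    A residue-id pair (i, j) with ``|i - j| >= min_sep`` is a contact iff
    the Cβ–Cβ distance (Cα for glycine) is below the cutoff for the two
    amino-acid types. With ``cross_chain`` the pair is a contact if any
    chain combination (including between copies in an expanded assembly)
    satisfies the rule; each residue-id pair is recorded at most once.
    """
    if isinstance(cutoffs, (int, float)):
        cutoffs = CutoffTable(float(cutoffs))
    chains = s.chains if cross_chain else s.chains[:1]
    contacts: set[tuple[int, int]] = set()
    for ci in range(len(chains)):
        for cj in range(ci, len(chains)):
            a, b = chains[ci], chains[cj]
            d = np.linalg.norm(a.cb[:, None, :] - b.cb[None, :, :], axis=2)
            for ia in range(len(a)):
                for ib in range(len(b)):
                    ri, rj = int(a.res_ids[ia]), int(b.res_ids[ib])
                    if ri == rj or abs(ri - rj) < min_sep:
                        continue
                    if d[ia, ib] < cutoffs(a.res_names[ia], b.res_names[ib]):
                        contacts.add(tuple(sorted((ri, rj))))
    return ContactMap(s.length, frozenset(contacts),
                      definition=f"CB-CB < cutoff (uniform {cutoffs.uniform} A)"
                      + (" cross-chain" if cross_chain else ""))


@dataclass(frozen=True)
class RcReport:
    """Rc value plus the per-pair satisfaction diagnostics."""

    rc: float
    observed: float
    expected: float
    satisfied: tuple[tuple[int, int], ...]
    violated: tuple[tuple[int, int], ...]

    def __float__(self) -> float:
        return self.rc


def rc_score(preds: ContactPredictionSet, s: Structure, min_sep: int = 6,
             cutoffs: CutoffTable | float = DEFAULT_CUTOFFS,
             cross_chain: bool = True) -> RcReport:
    """Observed / expected total normalized contact score of a model.

    Over predicted pairs with separation >= ``min_sep`` whose residues
    are resolved in the structure (the shortest-overlap rule):
    ``observed = sum(sco * [pair in contact])``,
    ``expected = sum(sco * P)``. Probabilities must have been assigned.
    Raises ``ValueError`` when the expected total is zero.
    """
    if not preds.has_probabilities:
        raise ValueError("prediction set lacks probabilities; "
                         "run score_probabilities first")
    cmap = contact_map(s, cutoffs=cutoffs, cross_chain=cross_chain)
    present = s.residue_ids
    observed = expected = 0.0
    satisfied: list[tuple[int, int]] = []
    violated: list[tuple[int, int]] = []
    for row in preds.table.itertuples():
        i, j = int(row.i), int(row.j)
        if row.sep < min_sep or i not in present or j not in present:
            continue
        expected += row.sco * row.prob
        if (i, j) in cmap:
            observed += row.sco
            satisfied.append((i, j))
        else:
            violated.append((i, j))
    if expected == 0.0:
        raise ValueError("expected total score is zero; Rc is undefined")
    return RcReport(observed / expected, observed, expected,
                    tuple(satisfied), tuple(violated))


def top_contact_precision(preds: ContactPredictionSet, native: ContactMap,
                          k: int, min_sep: int = 6) -> float:
    """Fraction of the top-k pairs (by sco, sep >= min_sep) that are native."""
    t = preds.table[preds.table["sep"] >= min_sep]
    if k > len(t):
        raise ValueError(f"k={k} exceeds the {len(t)} available pairs")
    top = t.nlargest(k, "sco", keep="first")
    hits = sum((int(r.i), int(r.j)) in native for r in top.itertuples())
    return hits / k if k else 0.0
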