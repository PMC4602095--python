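"""End-to-end pipelines: MSA -> predictions -> restraints, and Rc evaluation.

Two orchestrated paths tie the toolkit together:

* :func:`predict_pipeline` — filter an alignment, fit the Potts model,
  normalize scores, calibrate probabilities, and emit restraint files,
  writing every intermediate table plus a manifest.
* :func:`evaluate_pipeline` — score a structural model against a
  prediction table with the Rc metric and attach an advisory verdict
  (native-like above 0.7, poor below 0.3, ambiguous between).

Selection rules (alignment depth of at least 4 sequences per residue,
Rc of at least 0.7) are advisory: the pipeline warns and labels but
never refuses to run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import calibration, msa, potts, restraints as rst
from .calibration import AccuracyModel
from .structure_contacts import CutoffTable, read_structure, rc_score

__all__ = ["RunConfig", "PipelineError", "predict_pipeline", "evaluate_pipeline"]

log = logging.getLogger("coevkit")

RC_NATIVE_CUTOFF = 0.7
RC_RANDOM_CEILING = 0.3
MIN_DEPTH_PER_LENGTH = 4.0


class PipelineError(RuntimeError):
    """An error in a pipeline stage, annotated with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All tunable thresholds of the prediction and evaluation pipelines."""

    # msa filtering
    max_gap_frac: float = 0.75
    max_identity: float = 0.90
    min_coverage: float = 0.75
    # potts fit
    reg_fields: float = 0.01
    reg_couplings: float | None = None  # None -> 0.2 * (L - 1)
    max_iter: int = 100
    tol: float = 1e-4
    apc: bool = True
    seq_weighting: bool = True
    # calibration
    amplitude: float = 0.89
    slope_coef: float = 0.58
    ratio_exp: float = 0.50
    offset_coef: float = 5.46
    offset_exp: float = -0.53
    background: str = "default"  # "default" (toy-fold empirical), "zero", or a float as str
    # contacts / restraints
    cutoff: float = 8.0
    restraint_slope: float = 2.0
    restraint_intercept: float = -1.0
    stages: tuple[float, ...] = (12, 23, math.inf)
    min_sep_rc: int = 6
    # trimming
    msd_cut: float = 2.0
    halfwin: int = 3
    sigma: float = 1.5
    # misc
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if not 0 < self.max_gap_frac <= 1:
            raise ValueError("max_gap_frac must be in (0, 1]")
        if not 0 < self.max_identity <= 1 or not 0 <= self.min_coverage <= 1:
            raise ValueError("identity/coverage thresholds must be fractions")
        if self.msd_cut <= 0 or self.cutoff <= 0 or self.restraint_slope <= 0:
            raise ValueError("cutoffs, slopes and msd_cut must be positive")

    def accuracy_model(self) -> AccuracyModel:
        base = AccuracyModel(self.amplitude, self.slope_coef, self.ratio_exp,
                             self.offset_coef, self.offset_exp)
        if self.background == "default":
            from .synthetic import default_accuracy_model
            return base.with_background(default_accuracy_model().background)
        if self.background == "zero":
            return base
        const = float(self.background)
        return base.with_background(lambda sep: const)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["stages"] = [None if math.isinf(s) else s for s in self.stages]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "stages" in d:
            d["stages"] = tuple(math.inf if s is None else s for s in d["stages"])
        return cls(**d)

    def digest(self) -> str:
        return hashlib.sha256(repr(dataclasses.asdict(self)).encode()).hexdigest()[:12]


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as e:  # noqa: BLE001 - annotate and re-raise
                raise PipelineError(name, e) from e
        return wrapped
    return deco


def _query_sequence(aln: msa.Alignment) -> str:
    """Amino-acid type per column: the query's letter, or the column
    majority where the query is gapped."""
    from .alphabet import ALPHABET, GAP_STATE
    out = []
    for c in range(aln.length):
        s = int(aln.matrix[0, c])
        if s == GAP_STATE:
            col = aln.matrix[:, c]
            col = col[col != GAP_STATE]
            s = int(np.bincount(col).argmax()) if col.size else 0
        out.append(ALPHABET[s])
    return "".join(out)


def predict_pipeline(cfg: RunConfig, msa_path, outdir) -> dict:
    """Filter -> fit -> score -> normalize -> calibrate -> restraints.

    Writes the filtered alignment, raw score table, prediction table,
    staged and full constraint files, and a manifest; returns a dict of
    the output paths plus summary statistics. Deterministic given the
    same config and inputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    msa_path = Path(msa_path)
    fmt = "a3m" if msa_path.suffix.lower() == ".a3m" else "fasta"

    aln = _stage("read_alignment")(msa.read_alignment)(msa_path, format=fmt)
    aln = _stage("filter_gap_columns")(msa.filter_gap_columns)(
        aln, cfg.max_gap_frac)
    aln = _stage("filter_redundant_sequences")(msa.filter_redundant_sequences)(
        aln, cfg.max_identity, cfg.min_coverage)
    per_len = msa.depth_ratio(aln, "per_len")
    per_sqrt = msa.depth_ratio(aln, "per_sqrt_len")
    log.info("filtered alignment: depth=%d length=%d seq/len=%.2f seq/sqrt(len)=%.2f",
             aln.depth, aln.length, per_len, per_sqrt)
    if per_len < MIN_DEPTH_PER_LENGTH:
        log.warning("alignment depth %.2f per residue is below the advisory "
                    "threshold of %.0f; predictions may be unreliable",
                    per_len, MIN_DEPTH_PER_LENGTH)
    msa.write_fasta(aln, outdir / "filtered.fasta")

    fit = _stage("fit_plm")(potts.fit_plm)(
        aln, reg_fields=cfg.reg_fields, reg_couplings=cfg.reg_couplings,
        max_iter=cfg.max_iter, tol=cfg.tol, seq_weighting=cfg.seq_weighting)
    scores = potts.coupling_score_matrix(fit, apc=cfg.apc)
    potts.write_score_table(scores, outdir / "scores.tsv")

    preds = _stage("normalize_scores")(calibration.normalize_scores)(
        scores, depth=aln.depth)
    preds = _stage("score_probabilities")(calibration.score_probabilities)(
        preds, cfg.accuracy_model())
    calibration.write_prediction_table(preds, outdir / "predictions.tsv")

    seq = _query_sequence(aln)
    params = rst.RestraintParams(CutoffTable(cfg.cutoff), cfg.restraint_slope)
    restraint_list = _stage("build_restraints")(rst.build_restraints)(
        preds, seq, params, intercept=cfg.restraint_intercept)
    files = rst.write_constraints(restraint_list, outdir / "constraints.cst",
                                  dialect="rosetta_sigmoid", stages=cfg.stages)
    rst.write_constraints(restraint_list, outdir / "constraints.cst")

    manifest = {
        "config_digest": cfg.digest(),
        "input": str(msa_path),
        "depth": aln.depth, "length": aln.length,
        "seq_per_len": per_len, "seq_per_sqrt_len": per_sqrt,
        "n_pairs": len(preds.table), "n_restraints": len(restraint_list),
        "outputs": [str(outdir / "filtered.fasta"), str(outdir / "scores.tsv"),
                    str(outdir / "predictions.tsv"),
                    str(outdir / "constraints.cst")] + [str(f) for f in files],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def evaluate_pipeline(cfg: RunConfig, preds_path, structure_path,
                      out_path=None) -> dict:
    """Rc of a model against a prediction table, with an advisory label."""
    preds = _stage("read_prediction_table")(calibration.read_prediction_table)(
        preds_path)
    if not preds.has_probabilities:
        raise PipelineError("score_probabilities",
                            ValueError("prediction table lacks probabilities"))
    s = _stage("read_structure")(read_structure)(structure_path)
    report = _stage("rc_score")(rc_score)(
        preds, s, min_sep=cfg.min_sep_rc, cutoffs=CutoffTable(cfg.cutoff))
    if report.rc >= RC_NATIVE_CUTOFF:
        label = "native-like"
    elif report.rc <= RC_RANDOM_CEILING:
        label = "poor"
    else:
        label = "ambiguous"
    out = {
        "rc": report.rc, "observed": report.observed,
        "expected": report.expected, "label": label,
        "n_satisfied": len(report.satisfied), "n_violated": len(report.violated),
        "satisfied": [list(p) for p in report.satisfied],
        "violated": [list(p) for p in report.violated],
    }
    if out_path is not None:
        Path(out_path).write_text(json.dumps(out, indent=2))
    return out
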