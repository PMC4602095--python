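"""Shared fixtures: toy folds, planted alignments, and one expensive
contact-recovery study reused by several tests."""

from __future__ import annotations

import math

import numpy as np
import pytest

from coevkit.calibration import normalize_scores, score_probabilities
from coevkit.potts import PottsPseudolikelihood
from coevkit.structure_contacts import contact_map
from coevkit.synthetic import (ToyFoldSpec, default_accuracy_model,
                               make_toy_fold, sample_potts_alignment)


@pytest.fixture(scope="session")
def bundle80():
    """A length-80 helix-bundle toy fold with its contact map."""
    fold = make_toy_fold(ToyFoldSpec(80, "helix_bundle", seed=1))
    return fold, contact_map(fold)


@pytest.fixture(scope="session")
def recovery_study():
    """End-to-end contact recovery at L=60, depth 8*sqrt(L), strength 2.

    Returns (fold, contact map, alignment, fit results, calibrated
    prediction set); shared because the Potts fit is the expensive step.
    """
    L = 60
    fold = make_toy_fold(ToyFoldSpec(L, "helix_bundle", seed=3))
    cmap = contact_map(fold)
    depth = round(8 * math.sqrt(L))
    aln = sample_potts_alignment(cmap, depth, coupling_strength=2.0, seed=33)
    results = PottsPseudolikelihood(aln).fit()
    preds = normalize_scores(results.score_matrix(), depth=depth)
    preds = score_probabilities(preds, default_accuracy_model())
    return fold, cmap, aln, results, preds


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
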