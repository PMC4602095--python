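"""Superposition, TM-score, convergence, selection, and trimming."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from coevkit.ensemble import (ModelEnsemble, classify_mean_tm,
                              convergence_class, kabsch_superpose,
                              pairwise_tm_matrix, rmsd_over_subset,
                              select_central_model, select_top_fraction,
                              superpose_to_mean, tm_score, trim_unreliable)
from coevkit.restraints import Restraint
from coevkit.structure_contacts import Structure, contact_map
from coevkit.synthetic import (ToyFoldSpec, cbeta_from_ca, make_toy_fold,
                               perturb_ensemble)


def _random_decoy(L, seed):
    """A self-crossing random walk: no defined fold."""
    rng = np.random.default_rng(seed)
    steps = rng.normal(size=(L - 1, 3))
    steps = 3.8 * steps / np.linalg.norm(steps, axis=1, keepdims=True)
    ca = np.vstack([[0, 0, 0], np.cumsum(steps, axis=0)])
    return Structure.single_chain("A" * L, ca, cbeta_from_ca(ca))


def _restraints_from_fold(fold, min_sep=3):
    cm = contact_map(fold)
    seq = fold.chains[0].res_names
    out = []
    for (i, j) in sorted(cm.contacts):
        if j - i < min_sep:
            continue
        out.append(Restraint(i, j,
                             "CA" if seq[i - 1] == "G" else "CB",
                             "CA" if seq[j - 1] == "G" else "CB",
                             weight=1.5, cutoff=8.0, slope=2.0))
    return out


class TestKabsch:
    def test_identical_sets_have_zero_rmsd(self, rng):
        a = rng.normal(size=(10, 3))
        R, t, rmsd = kabsch_superpose(a, a)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(R, np.eye(3), atol=1e-10)

    def test_recovers_applied_rotation(self, rng):
        a = rng.normal(size=(25, 3)) * 5
        R_true = Rotation.random(random_state=np.random.default_rng(3)).as_matrix()
        b = (a - a.mean(0)) @ R_true.T + np.array([4.0, -2.0, 7.0])
        R, t, rmsd = kabsch_superpose(a, b)
        assert rmsd <= 1e-6
        assert np.abs(R @ R_true - np.eye(3)).max() <= 1e-6

    def test_mirror_image_not_superposable(self, rng):
        a = rng.normal(size=(15, 3)) * 4
        b = a.copy()
        b[:, 0] *= -1
        _, _, rmsd = kabsch_superpose(a, b)
        assert rmsd > 0.5

    def test_degenerate_inputs_rejected(self):
        line = np.stack([np.arange(5.0), np.zeros(5), np.zeros(5)], axis=1)
        with pytest.raises(ValueError):
            kabsch_superpose(line, line + 1.0)
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestTMScore:
    def test_self_comparison_is_unity(self):
        fold = make_toy_fold(ToyFoldSpec(60, "helix_bundle", seed=4))
        assert tm_score(fold, fold) == pytest.approx(1.0)

    def test_rigid_motion_invariance(self):
        fold = make_toy_fold(ToyFoldSpec(50, "sheet_like", seed=5))
        c = fold.chains[0]
        R = Rotation.random(random_state=np.random.default_rng(9)).as_matrix()
        moved = Structure.single_chain(
            c.res_names, c.ca @ R.T + 11.0, c.cb @ R.T + 11.0,
            res_ids=c.res_ids)
        assert tm_score(moved, fold) == pytest.approx(1.0, abs=1e-6)

    def test_random_decoys_score_low(self):
        fold = make_toy_fold(ToyFoldSpec(100, "helix_bundle", seed=6))
        scores = [tm_score(_random_decoy(100, s), fold) for s in range(20)]
        assert max(scores) < 0.3

    def test_symmetric_average_matrix(self):
        models = [make_toy_fold(ToyFoldSpec(40, "helix_bundle", seed=s))
                  for s in (7, 8)] + [_random_decoy(40, 1)]
        M = pairwise_tm_matrix(models)
        assert np.allclose(M, M.T)
        assert np.allclose(np.diag(M), 1.0)
        assert ((M > 0) & (M <= 1)).all()


class TestConvergence:
    def test_identical_models_converge_at_unity(self):
        fold = make_toy_fold(ToyFoldSpec(40, "helix_bundle", seed=10))
        ens = perturb_ensemble(fold, 5, 0.0, seed=1)
        label, mean_tm = convergence_class(ens)
        assert label == "converged"
        assert mean_tm == pytest.approx(1.0, abs=1e-6)

    def test_independent_decoys_do_not_converge(self):
        models = tuple(_random_decoy(60, s) for s in range(5))
        label, mean_tm = convergence_class(ModelEnsemble(models))
        assert label == "not_converged"
        assert mean_tm < 0.5

    @pytest.mark.parametrize("mean_tm,expected", [
        (0.81, "converged"), (0.8, "substructure"), (0.65, "substructure"),
        (0.5, "substructure"), (0.49, "not_converged")])
    def test_boundaries_assigned_to_substructure(self, mean_tm, expected):
        assert classify_mean_tm(mean_tm) == expected

    def test_single_model_rejected(self):
        fold = make_toy_fold(ToyFoldSpec(40, "helix_bundle", seed=10))
        with pytest.raises(ValueError):
            convergence_class(ModelEnsemble((fold,)))


class TestSelection:
    def test_five_percent_of_hundred(self):
        fold = make_toy_fold(ToyFoldSpec(30, "helix_bundle", seed=12))
        ens = perturb_ensemble(fold, 100, 0.5, seed=2)
        top = select_top_fraction(ens, 0.05)
        assert len(top) == 5
        assert max(top.scores) <= np.partition(ens.scores, 5)[5]

    def test_full_fraction_is_identity(self):
        fold = make_toy_fold(ToyFoldSpec(30, "helix_bundle", seed=12))
        ens = perturb_ensemble(fold, 10, 0.5, seed=3)
        assert len(select_top_fraction(ens, 1.0)) == 10

    def test_ceiling_keeps_at_least_one(self):
        fold = make_toy_fold(ToyFoldSpec(30, "helix_bundle", seed=12))
        ens = perturb_ensemble(fold, 10, 0.5, seed=4)
        assert len(select_top_fraction(ens, 0.05)) == 1

    def test_missing_scores_rejected(self):
        fold = make_toy_fold(ToyFoldSpec(30, "helix_bundle", seed=12))
        ens = ModelEnsemble((fold, fold))
        with pytest.raises(ValueError):
            select_top_fraction(ens)


class TestCentralModel:
    def test_majority_structure_wins(self):
        fold = make_toy_fold(ToyFoldSpec(40, "helix_bundle", seed=13))
        c = fold.chains[0]
        rng = np.random.default_rng(0)
        y_ca = c.ca + rng.normal(0, 4.0, c.ca.shape)
        y = Structure.single_chain(c.res_names, y_ca, cbeta_from_ca(y_ca),
                                   res_ids=c.res_ids)
        ens = ModelEnsemble((fold, fold, y))
        central = select_central_model(ens)
        assert central is ens.models[0]

    def test_identical_models_return_first(self):
        fold = make_toy_fold(ToyFoldSpec(40, "helix_bundle", seed=13))
        ens = ModelEnsemble((fold, fold, fold))
        assert select_central_model(ens) is ens.models[0]

    def test_invariant_to_rigid_motion_of_one_model(self):
        fold = make_toy_fold(ToyFoldSpec(40, "helix_bundle", seed=14))
        ens = perturb_ensemble(fold, 6, 0.3, seed=5)
        choice1 = select_central_model(ens)
        k1 = next(k for k, m in enumerate(ens.models) if m is choice1)
        c = ens.models[2].chains[0]
        R = Rotation.random(random_state=np.random.default_rng(2)).as_matrix()
        moved = Structure.single_chain(c.res_names, c.ca @ R.T + 30.0,
                                       c.cb @ R.T + 30.0, res_ids=c.res_ids)
        models = list(ens.models)
        models[2] = moved
        k2 = [select_central_model(ModelEnsemble(tuple(models))) is m
              for m in models].index(True)
        assert k1 == k2


class TestTrimming:
    def test_clean_ensemble_keeps_everything(self):
        fold = make_toy_fold(ToyFoldSpec(60, "helix_bundle", seed=15))
        ens = perturb_ensemble(fold, 8, 0.05, seed=6)
        rs = _restraints_from_fold(fold)
        report = trim_unreliable(ens, rs)
        assert report.retained.all()
        assert report.reasons == {}

    def test_jittered_loop_flagged_mobile(self):
        fold = make_toy_fold(ToyFoldSpec(80, "helix_bundle", seed=16))
        sigma = np.full(80, 0.2)
        sigma[39:50] = 3.0  # residues 40-50 (1-based) jittered
        ens = perturb_ensemble(fold, 12, sigma, seed=7)
        rs = _restraints_from_fold(fold)
        report = trim_unreliable(ens, rs)
        mobile = {rid for rid, why in report.reasons.items() if "mobile" in why}
        assert mobile  # the loop is detected
        assert mobile <= set(range(37, 54))  # within the smoothing halo

    def test_msd_census_matches_brute_force(self):
        # oracle: recompute per-residue MSD directly from the superposed stack
        fold = make_toy_fold(ToyFoldSpec(50, "helix_bundle", seed=17))
        ens = perturb_ensemble(fold, 6, 0.8, seed=8)
        report = trim_unreliable(ens, _restraints_from_fold(fold))
        stack, mean = superpose_to_mean(ens)
        brute = np.array([
            np.mean([np.sum((stack[m, r] - mean[r]) ** 2)
                     for m in range(stack.shape[0])])
            for r in range(50)])
        assert np.allclose(report.msd_raw, brute, atol=1e-8)

    def test_unconstrained_region_flagged(self):
        fold = make_toy_fold(ToyFoldSpec(60, "helix_bundle", seed=18))
        ens = perturb_ensemble(fold, 6, 0.05, seed=9)
        rs = [r for r in _restraints_from_fold(fold)
              if r.i > 15 and r.j > 15]  # strip all restraints near the N terminus
        report = trim_unreliable(ens, rs)
        flagged = {rid for rid, why in report.reasons.items()
                   if "unconstrained" in why}
        assert 1 in flagged and 5 in flagged

    def test_violated_restraints_flagged(self):
        fold = make_toy_fold(ToyFoldSpec(60, "helix_bundle", seed=19))
        ens = perturb_ensemble(fold, 6, 0.05, seed=10)
        # fabricate restraints that the fold cannot satisfy: pairs far apart
        seq = fold.chains[0].res_names
        cm = contact_map(fold)
        bogus = []
        for i in range(1, 61):
            for j in range(i + 20, 61):
                if (i, j) not in cm and len(bogus) < 8:
                    bogus.append(Restraint(i, j, "CB", "CB", weight=1.5,
                                           cutoff=8.0, slope=2.0))
        report = trim_unreliable(ens, _restraints_from_fold(fold) + bogus)
        flagged = {rid for rid, why in report.reasons.items()
                   if "violated" in why}
        assert flagged

    def test_raising_cutoff_never_shrinks_retained_set(self):
        fold = make_toy_fold(ToyFoldSpec(60, "helix_bundle", seed=20))
        ens = perturb_ensemble(fold, 8, 1.2, seed=11)
        rs = _restraints_from_fold(fold)
        r1 = trim_unreliable(ens, rs, msd_cut=1.0)
        r2 = trim_unreliable(ens, rs, msd_cut=4.0)
        assert (r2.retained >= r1.retained).all()

    def test_out_of_range_restraints_rejected(self):
        fold = make_toy_fold(ToyFoldSpec(60, "helix_bundle", seed=20))
        ens = perturb_ensemble(fold, 4, 0.2, seed=12)
        bad = [Restraint(1, 99, "CB", "CB", weight=1.0, cutoff=8.0, slope=2.0)]
        with pytest.raises(ValueError):
            trim_unreliable(ens, bad)


class TestSubsetRMSD:
    def test_self_rmsd_zero_under_any_mask(self):
        fold = make_toy_fold(ToyFoldSpec(50, "helix_bundle", seed=21))
        assert rmsd_over_subset(fold, fold, range(1, 51)) == pytest.approx(0.0, abs=1e-9)
        assert rmsd_over_subset(fold, fold, [3, 9, 20, 40]) == pytest.approx(0.0, abs=1e-9)

    def test_masking_out_displaced_loop_improves_rmsd(self):
        fold = make_toy_fold(ToyFoldSpec(60, "helix_bundle", seed=22))
        c = fold.chains[0]
        ca = c.ca.copy()
        ca[20:30] += np.array([8.0, 5.0, 0.0])  # displace one loop
        model = Structure.single_chain(c.res_names, ca, cbeta_from_ca(ca),
                                       res_ids=c.res_ids)
        full = rmsd_over_subset(model, fold, range(1, 61))
        masked = rmsd_over_subset(model, fold,
                                  [r for r in range(1, 61) if not 21 <= r <= 30])
        assert masked < full

    def test_invariant_to_rigid_motion(self):
        fold = make_toy_fold(ToyFoldSpec(50, "helix_bundle", seed=23))
        c = fold.chains[0]
        R = Rotation.random(random_state=np.random.default_rng(4)).as_matrix()
        moved = Structure.single_chain(c.res_names, c.ca @ R.T - 9.0,
                                       c.cb @ R.T - 9.0, res_ids=c.res_ids)
        assert rmsd_over_subset(moved, fold, range(1, 51)) == pytest.approx(0.0, abs=1e-6)

    def test_tiny_mask_rejected(self):
        fold = make_toy_fold(ToyFoldSpec(50, "helix_bundle", seed=23))
        with pytest.raises(ValueError):
            rmsd_over_subset(fold, fold, [1, 2])

    def test_trimmed_region_closer_to_truth_than_full_length(self):
        fold = make_toy_fold(ToyFoldSpec(60, "helix_bundle", seed=24))
        sigma = np.full(60, 0.2)
        sigma[44:56] = 3.5
        ens = perturb_ensemble(fold, 10, sigma, seed=13)
        report = trim_unreliable(ens, _restraints_from_fold(fold))
        central = select_central_model(ens)
        kept = report.retained_ids
        if len(kept) >= 3 and len(kept) < 60:
            assert rmsd_over_subset(central, fold, kept) <= \
                rmsd_over_subset(central, fold, range(1, 61))
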