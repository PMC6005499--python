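"""FitValue engine, drug-likeness filters, and the screening funnel."""
import itertools

import numpy as np
import pytest

from alloscreen import screen, synthetic
from alloscreen.chem import Molecule, compute_properties
from alloscreen.druglikeness import QED_PROPERTIES, QEDParams, lipinski_pass, qed
from alloscreen.chem import PropertyVector
from alloscreen.features import Hypothesis, PharmacophoreFeature
from alloscreen.screen import (FunnelConfig, best_fit, ligand_features,
                               map_and_fit, run_funnel, screen_library,
                               selectivity_screen)
from alloscreen.superpose import kabsch

from conftest import embedded, random_rotation


def _feats_at(h, displace=None):
    feats = [PharmacophoreFeature(f.type, np.array(f.center)) for f in h.features]
    if displace is not None:
        for i, d in displace.items():
            feats[i].center = feats[i].center + np.asarray(d)
    return feats


# --------------------------------------------------------------------------
# ligand features
# --------------------------------------------------------------------------

class TestLigandFeatures:
    @pytest.mark.parametrize("smiles, expected", [
        ("Oc1ccccc1", ["ARO", "HBA", "HBD"]),       # phenol
        ("CCCCCC", ["HYD"]),                        # hexane: one carbon group
        ("C", ["HYD"]),                             # methane
    ])
    def test_typing(self, smiles, expected):
        feats = ligand_features(embedded(smiles))
        assert sorted(f.type for f in feats) == expected

    def test_2d_only_molecule_rejected(self):
        with pytest.raises(ValueError, match="no 3D conformers"):
            ligand_features(Molecule.from_smiles("CCO"))


# --------------------------------------------------------------------------
# map_and_fit
# --------------------------------------------------------------------------

class TestMapAndFit:
    def test_perfect_placement_scores_total_weight(self, target_hypothesis):
        res = map_and_fit(_feats_at(target_hypothesis), target_hypothesis, 4)
        assert res.fit_value == pytest.approx(5.0, abs=1e-9)
        assert res.n_matched == 5

    def test_single_displacement_bounded(self, target_hypothesis):
        # one feature off by r/2: without re-superposition the score would be
        # exactly 5 - 0.25; the optimal superposition redistributes the
        # error, so the score lies in [4.75, 5)
        feats = _feats_at(target_hypothesis, displace={0: (0.75, 0, 0)})
        res = map_and_fit(feats, target_hypothesis, 4)
        assert res.n_matched == 5
        assert 4.75 <= res.fit_value < 5.0

    def test_too_few_compatible_features_gives_none(self, target_hypothesis):
        feats = _feats_at(target_hypothesis)[:3]
        assert map_and_fit(feats, target_hypothesis, 4) is None

    def test_min_features_floor(self, target_hypothesis):
        with pytest.raises(ValueError, match="min_features"):
            map_and_fit(_feats_at(target_hypothesis), target_hypothesis, 2)

    def test_rigid_motion_invariance(self, target_hypothesis):
        rng = np.random.default_rng(0)
        base = map_and_fit(_feats_at(target_hypothesis), target_hypothesis, 4)
        for _ in range(5):
            R = random_rotation(rng)
            t = rng.normal(0, 10, 3)
            feats = _feats_at(target_hypothesis)
            for f in feats:
                f.center = R @ f.center + t
            res = map_and_fit(feats, target_hypothesis, 4)
            assert res.fit_value == pytest.approx(base.fit_value, abs=1e-6)

    def test_pruned_equals_exhaustive(self):
        rng = np.random.default_rng(1)
        types = ["HBD", "HBA", "HYD", "ARO"]
        for _ in range(60):
            nh = int(rng.integers(3, 6))
            nl = int(rng.integers(3, 9))
            h = Hypothesis([PharmacophoreFeature(types[rng.integers(4)],
                                                 rng.uniform(0, 8, 3))
                            for _ in range(nh)], frame_of_reference="x")
            lig = [PharmacophoreFeature(types[rng.integers(4)],
                                        rng.uniform(0, 8, 3))
                   for _ in range(nl)]
            a = map_and_fit(lig, h, 3, prune=True)
            b = map_and_fit(lig, h, 3, prune=False)
            if a is None:
                assert b is None
            else:
                assert a.fit_value == pytest.approx(b.fit_value, abs=1e-9)
                assert a.n_matched == b.n_matched

    def test_noise_degrades_fit_in_expectation(self, target_hypothesis):
        rng = np.random.default_rng(2)
        means = []
        for sigma in (0.1, 0.3, 0.6):
            fits = []
            for _ in range(100):
                feats = _feats_at(target_hypothesis)
                for f in feats:
                    f.center = f.center + rng.normal(0, sigma, 3)
                res = map_and_fit(feats, target_hypothesis, 4)
                fits.append(res.fit_value if res else 0.0)
            means.append(np.mean(fits))
        assert means[0] > means[1] > means[2]


class TestBestFit:
    def test_best_conformer_wins(self, target_hypothesis):
        lib, _ = synthetic.gen_hit_library(target_hypothesis, n_hits=1,
                                           n_nonhits=0, seed=0)
        mol = lib[0]
        # add a worse conformer: same graph, uniformly shifted features would
        # be absorbed; instead scramble by a large random displacement
        conf = mol.rdmol.GetConformer(0)
        import rdkit.Chem as RC
        bad = RC.Conformer(conf)
        for i in range(mol.n_atoms):
            p = conf.GetAtomPosition(i)
            bad.SetAtomPosition(i, (p.x + (i % 3) * 2.0, p.y, p.z))
        mol.rdmol.AddConformer(bad, assignId=True)
        res = best_fit(mol, target_hypothesis, 4)
        assert res.conformer == 0
        assert res.fit_value == pytest.approx(5.0, abs=1e-9)

    def test_zero_conformers_is_error(self, target_hypothesis):
        with pytest.raises(ValueError, match="no conformers"):
            best_fit(Molecule.from_smiles("CCO"), target_hypothesis, 4)

    def test_planted_hit_noise_bound(self, target_hypothesis):
        # noise 0.1 Å, radius 1.5 Å: each term loses at most ~(d/r)^2 with
        # d <= a few sigma; the spec's bound uses the per-feature noise level
        lib, gt = synthetic.gen_hit_library(target_hypothesis, n_hits=5,
                                            n_nonhits=0, noise_sd=0.1, seed=3)
        bound = 5 * (1 - (0.5 / 1.5) ** 2)   # generous 5-sigma displacement
        for mol in lib:
            res = best_fit(mol, target_hypothesis, 4)
            assert res is not None and res.fit_value >= bound


# --------------------------------------------------------------------------
# drug-likeness
# --------------------------------------------------------------------------

class TestLipinski:
    @pytest.mark.parametrize("mw, alogp, hbd, hba, ok", [
        (400.0, 3.0, 2, 5, True),
        (600.0, 3.0, 2, 5, False),
        (500.0, 5.0, 5, 10, True),   # inclusive bounds
        (400.0, 5.1, 0, 0, False),
    ])
    def test_rule_of_five(self, mw, alogp, hbd, hba, ok):
        p = PropertyVector(mw=mw, alogp=alogp, hbd=hbd, hba=hba, psa=80.0,
                           rotb=5, arom=1)
        assert lipinski_pass(p) is ok


class TestQED:
    def test_identities_and_bounds(self):
        params = QEDParams.default()
        p = compute_properties(Molecule.from_smiles("CC(=O)Nc1ccc(O)cc1"))
        out = qed(p, params)
        d = params.desirabilities(p)
        vals = list(d.values())
        for key in ("unweighted", "weighted"):
            assert 0 < out[key] <= 1
            assert min(vals) - 1e-12 <= out[key] <= max(vals) + 1e-12
        # unweighted equals the geometric mean
        assert out["unweighted"] == pytest.approx(
            np.exp(np.mean(np.log(vals))), rel=1e-12)

    def test_equal_weights_match_unweighted(self):
        params = QEDParams.unit_weights()
        p = compute_properties(Molecule.from_smiles("CCOC(=O)c1ccccc1N"))
        out = qed(p, params)
        assert out["weighted"] == pytest.approx(out["unweighted"], rel=1e-12)

    def test_constant_desirability_identity(self):
        # d_i = c for all i -> QED = c (checked through the formula core)
        logs = np.log(np.full(7, 0.37))
        assert np.exp(logs.mean()) == pytest.approx(0.37, rel=1e-12)

    def test_known_mixture_value(self):
        # one property at 0.25, six at 1.0, equal weights -> 0.25**(1/7)
        d = np.array([0.25, 1, 1, 1, 1, 1, 1])
        got = float(np.exp(np.log(d).mean()))
        assert got == pytest.approx(0.8203, abs=2e-4)


# --------------------------------------------------------------------------
# library screening and funnel
# --------------------------------------------------------------------------

class TestScreenLibrary:
    def test_planted_hits_recovered(self, target_hypothesis):
        lib, gt = synthetic.gen_hit_library(target_hypothesis, n_hits=5,
                                            n_nonhits=20, seed=0)
        rep = screen_library(lib, target_hypothesis, threshold=2.94,
                             min_features=4)
        assert rep.n_hits == 5
        assert all(gt.labels[i] == "hit" for i in rep.hits)
        assert rep.rows["id"].tolist() == [m.id for m in lib]  # order kept

    def test_threshold_zero_and_monotonicity(self, target_hypothesis):
        lib, _ = synthetic.gen_hit_library(target_hypothesis, n_hits=4,
                                           n_nonhits=8, seed=1)
        counts = [screen_library(lib, target_hypothesis, th, 4).n_hits
                  for th in (0.0, 2.0, 4.0, 5.0, 5.5)]
        assert counts[0] >= counts[1] >= counts[2] >= counts[3] >= counts[4]
        mappable = sum(1 for m in lib
                       if best_fit(m, target_hypothesis, 4) is not None)
        assert counts[0] == mappable

    def test_inclusive_threshold(self, target_hypothesis):
        lib, _ = synthetic.gen_hit_library(target_hypothesis, n_hits=1,
                                           n_nonhits=0, seed=2)
        rep = screen_library(lib, target_hypothesis, threshold=5.0,
                             min_features=4)
        assert rep.n_hits == 1  # fit exactly 5.0 counts as a hit


class TestSelectivity:
    def test_dual_binders_removed(self, target_hypothesis, anti_hypothesis):
        lib, gt = synthetic.gen_hit_library(target_hypothesis, n_hits=5,
                                            n_nonhits=10, n_dual=3,
                                            anti_h=anti_hypothesis, seed=1)
        rep = selectivity_screen(lib, target_hypothesis, 2.94,
                                 anti_hypothesis, 3.66, 4)
        assert int(rep.rows["hit_target"].sum()) == 5
        assert int(rep.rows["hit_anti"].sum()) == 3
        assert rep.n_hits == 2
        assert all(gt.labels[i] == "hit" for i in rep.hits)


class TestFunnel:
    def test_stage_counts_non_increasing(self, target_hypothesis,
                                         anti_hypothesis):
        lib, gt = synthetic.gen_hit_library(target_hypothesis, n_hits=6,
                                            n_nonhits=12, n_dual=2,
                                            anti_h=anti_hypothesis, seed=4)
        cfg = FunnelConfig(fit_threshold_target=2.94, fit_threshold_anti=3.66,
                           min_features=4, qed_threshold=0.0)
        rep = run_funnel(lib, cfg, target_hypothesis, anti_hypothesis)
        counts = [len(ids) for _, ids in rep.stages]
        assert counts[0] == 18
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        # target stage keeps exactly the planted hits that survived Lipinski
        names = [n for n, _ in rep.stages]
        assert names[:2] == ["input", "lipinski"]
        assert "target_pharmacophore" in names and "qed" in names

    def test_hooks_are_pass_through_tables(self, target_hypothesis):
        lib, _ = synthetic.gen_hit_library(target_hypothesis, n_hits=3,
                                           n_nonhits=3, seed=5)
        drop = {lib[0].id}
        cfg = FunnelConfig(qed_threshold=0.0, lipinski=False)
        rep = run_funnel(lib, cfg, target_hypothesis,
                         hooks={"toxicity": lambda i: i not in drop})
        assert "toxicity" in rep.counts
        assert lib[0].id not in rep.survivors()

    def test_all_thresholds_zero_keeps_mappable(self, target_hypothesis):
        lib, _ = synthetic.gen_hit_library(target_hypothesis, n_hits=3,
                                           n_nonhits=5, seed=6)
        cfg = FunnelConfig(fit_threshold_target=0.0, qed_threshold=0.0,
                           lipinski=False)
        rep = run_funnel(lib, cfg, target_hypothesis)
        mappable = {m.id for m in lib if best_fit(m, target_hypothesis, 4)}
        assert set(rep.survivors()) == mappable

    def test_empty_library_rejected(self, target_hypothesis):
        with pytest.raises(ValueError, match="non-empty"):
            screen_library([], target_hypothesis, 1.0, 4)
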