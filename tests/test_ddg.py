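"""Fermi algebra, feature construction, cystine filtering, training."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import stabscan as ss
from stabscan.ddg import (FEATURE_DIM, DownstreamConfig, DownstreamModel,
                          Ensemble, FermiParams, aa_frequencies,
                          annotate_disulfides, build_features,
                          convert_rosetta_units, fermi_transform,
                          filter_training_variants, inverse_fermi, predict_ddg,
                          train_downstream)


class TestFermi:
    def test_midpoint_is_exactly_half(self):
        assert fermi_transform(3.0) == 0.5

    def test_value_from_direct_evaluation(self):
        # 1 / (1 + e^{-0.4 (-1 - 3)}) = 1 / (1 + e^{1.6})
        assert fermi_transform(-1.0) == pytest.approx(1.0 / (1.0 + np.exp(1.6)),
                                                      abs=1e-12)

    def test_strictly_increasing(self):
        xs = np.linspace(-10, 17, 1000)
        ys = fermi_transform(xs)
        assert np.all(np.diff(ys) > 0)
        assert fermi_transform(7.0) > fermi_transform(3.0) > fermi_transform(-1.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=-10.0, max_value=17.0))
    def test_round_trip(self, x):
        assert inverse_fermi(fermi_transform(x)) == pytest.approx(x, abs=1e-9)

    def test_inverse_midpoint(self):
        assert inverse_fermi(0.5) == pytest.approx(3.0, abs=1e-12)

    def test_clamping_logged_and_applied(self, caplog):
        with caplog.at_level(logging.INFO, logger="stabscan.ddg"):
            v = inverse_fermi(1e-6)
        assert v == inverse_fermi(1e-4)
        assert any("clamped" in r.message for r in caplog.records)

    def test_nonpositive_beta_rejected(self):
        with pytest.raises(ValueError):
            FermiParams(beta=0.0)


@pytest.mark.parametrize("raw,expected", [(2.9, 1.0), (0.0, 0.0), (-5.8, -2.0)])
def test_rosetta_unit_conversion(raw, expected):
    assert convert_rosetta_units(raw) == pytest.approx(expected, abs=1e-12)


class TestFrequencies:
    def test_all_alanine(self):
        st_ = ss.make_toy_structure(ss.FixtureSpec(n_residues=5,
                                                   sequence="AAAAA"))
        f = aa_frequencies([st_])
        assert f[0] == 1.0 and f.sum() == 1.0

    def test_matches_direct_count(self, helix30):
        f = aa_frequencies([helix30])
        seq = [s.wt_aa for s in ss.residue_sites(helix30)]
        for i, aa in enumerate(ss.AA_ALPHABET):
            assert f[i] == pytest.approx(seq.count(aa) / len(seq), abs=1e-12)
        assert f.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            aa_frequencies([ss.Structure(source_id="x", chain_id="A")])


class TestFeatures:
    def test_length_and_block_layout(self):
        emb = np.arange(100.0)
        freqs = np.linspace(0.01, 0.09, 20)
        v = build_features(emb, "A", "W", freqs)
        assert v.shape == (FEATURE_DIM,)
        assert np.array_equal(v[:100], emb)
        assert v[100] == 1.0 and v[100:120].sum() == 1.0       # wt block: A
        assert v[120 + ss.AA_INDEX["W"]] == 1.0 and v[120:140].sum() == 1.0
        assert v[140] == freqs[0] and v[141] == freqs[ss.AA_INDEX["W"]]

    def test_swapping_wt_and_mut_swaps_blocks(self):
        emb = np.zeros(100)
        freqs = np.linspace(0.01, 0.09, 20)
        a = build_features(emb, "C", "Y", freqs)
        b = build_features(emb, "Y", "C", freqs)
        assert np.array_equal(a[100:120], b[120:140])
        assert np.array_equal(a[120:140], b[100:120])
        assert (a[140], a[141]) == (b[141], b[140])

    def test_self_substitution_has_identical_blocks(self):
        v = build_features(np.zeros(100), "G", "G", np.full(20, 0.05))
        assert np.array_equal(v[100:120], v[120:140])

    def test_non_canonical_rejected(self):
        with pytest.raises(ValueError, match="non-canonical"):
            build_features(np.zeros(100), "X", "A", np.full(20, 0.05))
        with pytest.raises(ValueError, match="length 100"):
            build_features(np.zeros(99), "A", "C", np.full(20, 0.05))


class TestCystineFilter:
    def test_bonded_pair_detected_and_removed(self):
        st_ = ss.make_disulfide_pair_structure()
        bonded = annotate_disulfides(st_)
        assert len(bonded) == 2
        tab = ss.make_synthetic_ddg(st_, seed=0, noise_sd=0.0)
        kept = filter_training_variants(tab, {st_.source_id: bonded})
        assert len(tab) - len(kept) == 2 * 19
        assert not set(kept["residue_index"]) & bonded

    def test_free_cysteine_retained(self):
        st_ = ss.make_toy_structure(
            ss.FixtureSpec(n_residues=9, sequence="AAAACAAAA"))
        assert annotate_disulfides(st_) == set()
        tab = ss.make_synthetic_ddg(st_, seed=0, noise_sd=0.0)
        kept = filter_training_variants(tab, {st_.source_id: set()})
        assert len(kept) == len(tab)

    def test_no_cysteines_is_identity(self):
        st_ = ss.make_toy_structure(
            ss.FixtureSpec(n_residues=6, sequence="AGVLIW"))
        tab = ss.make_synthetic_ddg(st_, seed=0, noise_sd=0.0)
        kept = filter_training_variants(
            tab, {st_.source_id: annotate_disulfides(st_)})
        pd.testing.assert_frame_equal(kept, tab)


class _StubModel:
    def __init__(self, value):
        self.value = value

    def predict_scores(self, features):
        return np.full(np.atleast_2d(features).shape[0], self.value)


def _stub_ensemble(values):
    cfg = DownstreamConfig(seeds=tuple(range(len(values))))
    return Ensemble(models=[_StubModel(v) for v in values], config=cfg,
                    frequencies=np.full(20, 0.05))


class TestEnsembleMedian:
    def test_identical_models_equal_single_model(self):
        feats = np.zeros(FEATURE_DIM)
        single = predict_ddg(_stub_ensemble([0.37]), feats)
        trio = predict_ddg(_stub_ensemble([0.37, 0.37, 0.37]), feats)
        assert trio.score_fermi == single.score_fermi
        assert trio.ddg == single.ddg

    def test_three_model_median_midpoint(self):
        rec = predict_ddg(_stub_ensemble([0.2, 0.5, 0.9]), np.zeros(FEATURE_DIM))
        assert rec.score_fermi == 0.5
        assert rec.ddg == pytest.approx(3.0, abs=1e-12)
        assert rec.per_model_scores == [0.2, 0.5, 0.9]

    def test_order_invariance(self):
        for perm in ([0.9, 0.2, 0.5], [0.5, 0.9, 0.2]):
            rec = predict_ddg(_stub_ensemble(perm), np.zeros(FEATURE_DIM))
            assert rec.score_fermi == 0.5

    def test_duplicating_every_model_preserves_median(self):
        base = [0.2, 0.5, 0.9]
        rec1 = predict_ddg(_stub_ensemble(base), np.zeros(FEATURE_DIM))
        rec2 = predict_ddg(_stub_ensemble(base * 2), np.zeros(FEATURE_DIM))
        assert rec1.score_fermi == rec2.score_fermi

    def test_flags(self):
        rec = predict_ddg(_stub_ensemble([0.5]), np.zeros(FEATURE_DIM),
                          wt_aa="C", mut_aa="C")
        assert rec.wt_is_cysteine and rec.self_substitution


@pytest.fixture(scope="module")
def tiny_training_problem(helix30, repr_reduced):
    tab = ss.make_synthetic_ddg(helix30, seed=0, noise_sd=0.1)
    freqs = aa_frequencies([helix30])
    sites = {s.residue_index: s for s in ss.residue_sites(helix30)}
    embs = {r: repr_reduced.embed(ss.featurize_site(helix30, sites[r]))
            for r in tab["residue_index"].unique()}
    feats = np.stack([build_features(embs[r.residue_index], r.wt_aa, r.mut_aa,
                                     freqs) for r in tab.itertuples()])
    n = len(tab)
    pids = ["p_train"] * (n - 120) + ["p_val"] * 120
    return feats, tab["ddg_kcal_per_mol"].to_numpy(), pids


class TestTraining:
    def test_leakage_and_unit_guards(self, tiny_training_problem):
        feats, targets, pids = tiny_training_problem
        cfg = DownstreamConfig(seeds=(0,), max_epochs=1)
        with pytest.raises(ValueError, match="leakage"):
            train_downstream(feats, targets, pids, ["p_train", "p_val"],
                             ["p_val"], cfg)
        bad = targets.copy()
        bad[0] = 99.0          # raw (unconverted) energy sneaking in
        with pytest.raises(ValueError, match="unit"):
            train_downstream(feats, bad, pids, ["p_train"], ["p_val"], cfg)

    def test_same_seed_identical_distinct_seeds_differ(self, tiny_training_problem):
        feats, targets, pids = tiny_training_problem
        cfg = DownstreamConfig(seeds=(0, 1), max_epochs=2, patience=2)
        e1 = train_downstream(feats, targets, pids, ["p_train"], ["p_val"], cfg)
        e2 = train_downstream(feats, targets, pids, ["p_train"], ["p_val"], cfg)
        p1 = [p.value for p in e1.models[0].net.params()]
        p2 = [p.value for p in e2.models[0].net.params()]
        assert all(np.array_equal(a, b) for a, b in zip(p1, p2))
        q = [p.value for p in e1.models[1].net.params()]
        assert not all(np.array_equal(a, b) for a, b in zip(p1, q))

    def test_overfits_small_variant_set(self, tiny_training_problem):
        feats, targets, pids = tiny_training_problem
        sub_feats = np.vstack([feats[:200], feats[-100:]])
        sub_targets = np.concatenate([targets[:200], targets[-100:]])
        sub_pids = ["p_train"] * 200 + ["p_val"] * 100
        cfg = DownstreamConfig(seeds=(0,), max_epochs=300, patience=300)
        ens = train_downstream(sub_feats, sub_targets, sub_pids,
                               ["p_train"], ["p_val"], cfg,
                               restore_best=False)
        pred = ens.models[0].predict_scores(sub_feats[:200])
        mae_f = np.abs(pred - fermi_transform(sub_targets[:200])).mean()
        assert mae_f < 0.02

    def test_ensemble_checkpoint_round_trip(self, tmp_path,
                                            tiny_training_problem):
        feats, targets, pids = tiny_training_problem
        cfg = DownstreamConfig(seeds=(0, 1), max_epochs=2, patience=2)
        ens = train_downstream(feats, targets, pids, ["p_train"], ["p_val"],
                               cfg)
        path = tmp_path / "ens.npz"
        ens.save(path)
        back = Ensemble.load(path)
        assert back.config == ens.config
        assert np.array_equal(back.frequencies, ens.frequencies)
        assert np.array_equal(back.predict_scores(feats[:5]),
                              ens.predict_scores(feats[:5]))


def test_config_invariants():
    with pytest.raises(ValueError):
        DownstreamConfig(seeds=())
    with pytest.raises(ValueError):
        DownstreamConfig(seeds=(0, 0))
    assert DownstreamConfig().ensemble_size == 10
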