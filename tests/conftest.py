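"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pytest

import stabscan as ss
from stabscan.ddg import DownstreamConfig, aa_frequencies, build_features, train_downstream
from stabscan.representation import RepresentationModel, reduced_config


@pytest.fixture(scope="session")
def helix30():
    return ss.make_toy_structure(ss.FixtureSpec(n_residues=30, seed=1))


@pytest.fixture(scope="session")
def bundle():
    return ss.make_toy_structure(
        ss.FixtureSpec(n_residues=84, geometry="compact_bundle", seed=2))


@pytest.fixture(scope="session")
def repr_reduced():
    """Untrained (seeded) reduced representation model — deterministic
    embeddings, adequate wherever trained weights are not the point."""
    return RepresentationModel(reduced_config(seed=0))


@pytest.fixture(scope="session")
def quick_ensemble(helix30, repr_reduced):
    """A 3-replica ensemble trained for a single epoch, to drive scans."""
    tab = ss.make_synthetic_ddg(helix30, seed=0, noise_sd=0.2)
    freqs = aa_frequencies([helix30])
    sites = {s.residue_index: s for s in ss.residue_sites(helix30)}
    embs = {r: repr_reduced.embed(ss.featurize_site(helix30, sites[r]))
            for r in tab["residue_index"].unique()}
    feats = np.stack([build_features(embs[r.residue_index], r.wt_aa, r.mut_aa,
                                     freqs)
                      for r in tab.itertuples()])
    pids = ["train_p"] * (len(tab) - 100) + ["val_p"] * 100
    cfg = DownstreamConfig(seeds=(0, 1, 2), max_epochs=1, patience=1)
    return train_downstream(feats, tab["ddg_kcal_per_mol"].to_numpy(), pids,
                            ["train_p"], ["val_p"], cfg, frequencies=freqs,
                            grid_spec=repr_reduced.grid_spec)
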