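"""Thermal sampler: invariants, topology preservation, statistics."""

import numpy as np
import pytest

from writhenet.atlas import seed_embedding
from writhenet.geomutils import min_nonadjacent_distance
from writhenet.oracle import classify_by_determinant
from writhenet.sampler import (SamplerConfig, decorrelation_check,
                               fit_persistence_length, thermalize)
from writhenet.writhe import global_writhe, total_curvature


class TestSnapshotInvariants:
    def test_bonds_and_excluded_volume(self, trefoil_ensemble):
        for conf in trefoil_ensemble[::20]:
            lengths = conf.bond_lengths()
            assert lengths.min() > 0.8 and lengths.max() < 1.2
            assert min_nonadjacent_distance(conf.positions, True, 1) >= 0.9 - 1e-9

    def test_trefoil_snapshots_satisfy_fary_milnor(self, trefoil_ensemble):
        # every nontrivially knotted conformation exceeds 4*pi
        curv = [total_curvature(c) for c in trefoil_ensemble]
        assert min(curv) > 4 * np.pi

    def test_unknot_snapshots_audit_trivial(self, five_knot_ensembles):
        rng = np.random.default_rng(0)
        for conf in five_knot_ensembles["0_1"][::40]:
            lab = classify_by_determinant(conf, 3, rng, fast=True)
            assert lab.det1 == 1

    def test_trefoil_snapshots_audit_knotted(self, trefoil_ensemble):
        rng = np.random.default_rng(1)
        for conf in trefoil_ensemble[::40]:
            assert classify_by_determinant(conf, 3, rng, fast=True).det1 == 3


class TestDeterminism:
    def test_identical_config_gives_identical_stream(self):
        emb = seed_embedding("3_1", 100)
        cfg = SamplerConfig(n_conformations=5, decorrelation_interval=10,
                            equilibration=50, seed=77)
        a = [c.positions for c in thermalize(emb, cfg)]
        b = [c.positions for c in thermalize(seed_embedding("3_1", 100), cfg)]
        for pa, pb in zip(a, b):
            assert np.array_equal(pa, pb)


class TestStatistics:
    def test_figure_eight_mean_writhe_is_zero(self, figure_eight_ensemble_500):
        # the 4_1 knot is amphichiral: its mean global writhe vanishes
        wr = np.array([global_writhe(c) for c in figure_eight_ensemble_500])
        se = wr.std(ddof=1) / np.sqrt(len(wr))
        assert abs(wr.mean()) <= 3 * se

    def test_persistence_length_recovered(self):
        emb = seed_embedding("0_1", 100)
        cfg = SamplerConfig(persistence_length=3.0, n_conformations=80,
                            decorrelation_interval=15, equilibration=400,
                            seed=5)
        confs = list(thermalize(emb, cfg))
        fitted = fit_persistence_length(confs)
        assert fitted == pytest.approx(3.0, rel=0.2)

    def test_production_interval_decorrelates(self, trefoil_ensemble):
        rep = decorrelation_check(trefoil_ensemble)
        assert rep["acf_writhe"][0] <= 0.2
        assert not np.isnan(rep["acf_rg"]).any()

    def test_shuffled_stream_uncorrelated(self, trefoil_ensemble):
        rng = np.random.default_rng(2)
        shuffled = list(trefoil_ensemble)
        rng.shuffle(shuffled)
        rep = decorrelation_check(shuffled)
        assert abs(rep["acf_rg"][0]) <= 3 / np.sqrt(len(shuffled))

    def test_consecutive_frames_strongly_correlated(self):
        emb = seed_embedding("3_1", 100)
        cfg = SamplerConfig(n_conformations=60, decorrelation_interval=1,
                            equilibration=300, seed=8, audit_fraction=0.0)
        confs = list(thermalize(emb, cfg))
        rep = decorrelation_check(confs)
        assert rep["acf_rg"][0] > 0.5
        assert rep["correlated"]


class TestConfigValidation:
    def test_bad_engine_rejected(self):
        with pytest.raises(ValueError):
            SamplerConfig(engine="molecular_magic")

    def test_lp_outside_tested_range_warns(self):
        with pytest.warns(UserWarning):
            SamplerConfig(persistence_length=0.6)

    def test_stream_shorter_than_lags_rejected(self, trefoil_ensemble):
        with pytest.raises(ValueError):
            decorrelation_check(trefoil_ensemble[:5], lag_grid=(1, 10))


class TestLangevinEngine:
    def test_short_run_preserves_geometry_and_topology(self):
        emb = seed_embedding("3_1", 100)
        cfg = SamplerConfig(n_conformations=3, decorrelation_interval=200,
                            equilibration=500, seed=4, engine="langevin",
                            langevin_dt=0.003)
        confs = list(thermalize(emb, cfg))
        assert len(confs) == 3
        rng = np.random.default_rng(0)
        for conf in confs:
            lengths = conf.bond_lengths()
            assert np.all(np.isfinite(conf.positions))
            assert lengths.max() < 1.5  # FENE bound R0
            assert classify_by_determinant(conf, 3, rng, fast=True).det1 == 3
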