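import numpy as np
import pandas as pd
import pytest

from coocnet.datatypes import SampleMetadata
from coocnet.ordination import (
    bray_curtis,
    dbrda,
    family_enrichment,
    forward_select,
    keystone_vs_environment,
    log_standardize_env,
)
from coocnet.simulate import SimulationConfig, plant_network, simulate_counts


class TestBrayCurtis:
    def test_identity_symmetry_bounds(self):
        rng = np.random.default_rng(0)
        X = rng.gamma(2, 1, size=(15, 8))
        d = bray_curtis(X).d
        assert np.allclose(np.diag(d), 0)
        assert np.allclose(d, d.T)
        assert d.min() >= 0 and d.max() <= 1

    def test_disjoint_support_is_one(self):
        X = np.array([[1.0, 2.0, 0.0, 0.0], [0.0, 0.0, 3.0, 1.0]])
        assert bray_curtis(X).d[0, 1] == pytest.approx(1.0)

    def test_worked_example(self):
        X = np.array([[1.0, 2.0, 3.0], [2.0, 0.0, 1.0]])
        assert bray_curtis(X).d[0, 1] == pytest.approx(5 / 9)

    def test_zero_sum_row_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis(np.array([[1.0, 2.0], [0.0, 0.0]]))


def legacy_fixture():
    """Deterministic fixture shared with the external reference run."""
    rng = np.random.RandomState(0)
    X = rng.gamma(2, 1, size=(20, 10))
    Z = rng.normal(size=(20, 2))
    return X, Z


class TestDbrda:
    # Reference values computed once with vegan::capscale (R 4.3.3) on the
    # legacy_fixture data; constrained inertia must agree.
    VEGAN_CONSTRAINED = 0.063833505284
    VEGAN_CANONICAL_EIG = (0.036406949724, 0.027426555560)
    VEGAN_TRACE_TOTAL = 1.406983984335

    def test_matches_vegan_capscale_reference(self):
        X, Z = legacy_fixture()
        res = dbrda(bray_curtis(X), Z)
        assert res.constrained_inertia == pytest.approx(
            self.VEGAN_CONSTRAINED, abs=1e-9
        )
        assert res.axes[0] == pytest.approx(self.VEGAN_CANONICAL_EIG[0], abs=1e-9)
        assert res.axes[1] == pytest.approx(self.VEGAN_CANONICAL_EIG[1], abs=1e-9)
        # vegan's net total = positive inertia minus negative-eigenvalue part
        assert res.total_inertia - res.negative_inertia == pytest.approx(
            self.VEGAN_TRACE_TOTAL, abs=1e-9
        )

    def test_inertia_decomposition_identity(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            X = rng.gamma(2, 1, size=(18, 9))
            Z = rng.normal(size=(18, 3))
            res = dbrda(bray_curtis(X), Z)
            unconstrained = res.total_inertia - res.constrained_inertia
            assert res.constrained_inertia + unconstrained == pytest.approx(
                res.total_inertia, abs=1e-8
            )
            assert 0 <= res.explained_fraction <= 1
            assert np.all(np.diff(res.axes) <= 1e-12)
            assert np.all(res.axes >= -1e-12)

    def test_random_constraints_explain_q_over_n_minus_1(self):
        """Shuffled (independent) constraints explain ~q/(n-1) of inertia."""
        rng = np.random.default_rng(2)
        n, q = 100, 4
        X = rng.gamma(2, 1, size=(n, 20))
        dist = bray_curtis(X)
        fracs = [
            dbrda(dist, rng.normal(size=(n, q))).explained_fraction
            for _ in range(30)
        ]
        assert np.mean(fracs) == pytest.approx(q / (n - 1), abs=0.015)

    def test_collinear_constraints_dropped_with_warning(self):
        X, Z = legacy_fixture()
        Z2 = np.column_stack([Z, Z[:, 0] * 2.0])
        with pytest.warns(UserWarning, match="collinear"):
            res = dbrda(bray_curtis(X), Z2)
        base = dbrda(bray_curtis(X), Z)
        assert res.constrained_inertia == pytest.approx(
            base.constrained_inertia, abs=1e-10
        )

    def test_zero_variance_constraint_rejected(self):
        X, _ = legacy_fixture()
        with pytest.raises(ValueError):
            dbrda(bray_curtis(X), np.ones((20, 1)))


class TestForwardSelect:
    def test_planted_driver_selected_first(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 60
            g = rng.normal(size=n)
            comm = np.exp(
                0.8 * np.outer(g, rng.normal(size=10))
                + 0.5 * rng.normal(size=(n, 10))
            )
            cand = pd.DataFrame(
                {"driver": g,
                 **{f"noise{i}": rng.normal(size=n) for i in range(5)}}
            )
            res = forward_select(bray_curtis(comm), cand, alpha=0.01,
                                 n_perm=199, seed=seed)
            if res.selected_constraints and \
                    res.selected_constraints[0]["name"] == "driver":
                hits += 1
        assert hits >= 9

    def test_pure_noise_rarely_selected(self):
        empty = 0
        rng = np.random.default_rng(3)
        for seed in range(40):
            X = rng.gamma(2, 1, size=(30, 10))
            cand = pd.DataFrame(rng.normal(size=(30, 5)),
                                columns=list("abcde"))
            res = forward_select(bray_curtis(X), cand, alpha=0.01,
                                 n_perm=199, seed=seed)
            empty += not res.selected_constraints
        assert empty >= 34  # best-of-5 selection inflates slightly above alpha

    def test_alpha_zero_selects_nothing(self):
        rng = np.random.default_rng(4)
        X = rng.gamma(2, 1, size=(25, 8))
        cand = pd.DataFrame({"a": rng.normal(size=25)})
        res = forward_select(bray_curtis(X), cand, alpha=0.0, n_perm=99, seed=0)
        assert res.selected_constraints == []
        assert res.explained_fraction == 0.0

    def test_never_selects_duplicate_of_selected(self):
        rng = np.random.default_rng(5)
        n = 50
        g = rng.normal(size=n)
        comm = np.exp(np.outer(g, rng.normal(size=8))
                      + 0.3 * rng.normal(size=(n, 8)))
        cand = pd.DataFrame({"g1": g, "g2": g * 3.0 + 1.0})
        res = forward_select(bray_curtis(comm), cand, alpha=0.05,
                             n_perm=199, seed=1)
        assert len(res.selected_constraints) == 1


class TestLogStandardize:
    def test_positive_columns_logged(self):
        env = pd.DataFrame({"a": [1.0, np.e, np.e ** 2]})
        out = log_standardize_env(env)
        assert np.allclose(out["a"], [0, 1, 2])

    def test_zero_containing_column_offset(self):
        env = pd.DataFrame({"a": [0.0, 2.0, 4.0]})
        out = log_standardize_env(env)
        assert np.all(np.isfinite(out["a"]))
        assert out["a"].iloc[0] == pytest.approx(np.log(1.0))  # half-min = 1


def _sim_for_ordination(seed=31):
    cfg = SimulationConfig(p_bacteria=25, p_phototroph=10, p_fungus=5,
                           n_samples=80, gradient_strength=0.0, seed=seed)
    net = plant_network(cfg)
    return cfg, net, simulate_counts(net, cfg)


class TestKeystoneVsEnvironment:
    def test_report_contract_three_fractions(self):
        _, net, sim = _sim_for_ordination()
        k16 = [t for t in net.hub_ids if t.startswith("ASV")] or \
            sim.table16.taxon_ids[:2]
        k18 = sim.table18.taxon_ids[:2]
        report = keystone_vs_environment(
            sim.table16, k16, k18, sim.table16, sim.table18, sim.metadata,
            n_perm=99, seed=0,
        )
        assert set(report) == {
            "bacterial_keystones", "eukaryotic_keystones", "environment"
        }
        for res in report.values():
            assert 0 <= res.explained_fraction <= 1

    def test_bacterial_keystones_outexplain_null_environment(self):
        """With no environmental structuring, hub (bacterial keystone)
        abundances explain more bacterial community variance than the
        environmental variables."""
        _, net, sim = _sim_for_ordination()
        deg = net.adjacency.sum(axis=1)
        order = np.argsort(-deg)
        k16 = [net.taxon_ids[i] for i in order
               if net.domain_labels[i] == "bacteria"][:5]
        k18 = sim.table18.taxon_ids[:3]
        report = keystone_vs_environment(
            sim.table16, k16, k18, sim.table16, sim.table18, sim.metadata,
            env_columns=["temperature", "conductivity", "ph", "turbidity"],
            n_perm=199, seed=1,
        )
        assert (
            report["bacterial_keystones"].explained_fraction
            > report["environment"].explained_fraction
        )

    def test_missing_keystone_rejected(self):
        _, _, sim = _sim_for_ordination()
        with pytest.raises(ValueError, match="absent"):
            keystone_vs_environment(
                sim.table16, ["missing"], sim.table18.taxon_ids[:1],
                sim.table16, sim.table18, sim.metadata, n_perm=99,
            )


def _enrichment_meta(n_per_cell, rng):
    meta, sid = [], 0
    for st in ("GFS", "TRIB"):
        for dg in ("pre2000", "post2000"):
            for _ in range(n_per_cell):
                meta.append(SampleMetadata(f"E{sid}", "Otemma", st, dg))
                sid += 1
    return meta


class TestFamilyEnrichment:
    def test_planted_shift_detected(self):
        """A 2-fold family shift between deglaciation levels (n=20/cell,
        CV~0.3) is detected at adjusted p < 0.05 in most runs."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            meta = _enrichment_meta(20, rng)
            n = len(meta)
            base = np.abs(rng.normal(1.0, 0.3, size=(4, n)))
            pre = np.array([m.deglaciation == "pre2000" for m in meta])
            base[0, pre] *= 2.0
            fam = pd.DataFrame(
                base / base.sum(axis=0),
                index=[f"Fam{i}" for i in range(4)],
                columns=[m.sample_id for m in meta],
            )
            res = family_enrichment(fam, meta)
            target = next(r for r in res if r.family == "Fam0")
            hits += target.adjusted_p["C(deglaciation)"] < 0.05
        assert hits >= 8

    def test_null_families_rarely_significant(self):
        sig = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            meta = _enrichment_meta(10, rng)
            n = len(meta)
            base = np.abs(rng.normal(1.0, 0.3, size=(5, n)))
            fam = pd.DataFrame(
                base / base.sum(axis=0),
                index=[f"Fam{i}" for i in range(5)],
                columns=[m.sample_id for m in meta],
            )
            for r in family_enrichment(fam, meta):
                sig += any(q < 0.05 for q in r.adjusted_p.values())
        assert sig <= 10  # 50 families x 3 effects under the null

    def test_single_family_bh_is_identity(self):
        rng = np.random.default_rng(9)
        meta = _enrichment_meta(5, rng)
        fam = pd.DataFrame(
            np.abs(rng.normal(1, 0.2, size=(1, len(meta)))),
            index=["OnlyFam"], columns=[m.sample_id for m in meta],
        )
        res = family_enrichment(fam, meta)[0]
        for eff, stats in res.factor_effects.items():
            assert res.adjusted_p[eff] == pytest.approx(stats["p"])

    def test_sparse_cells_skipped_with_warning(self):
        meta = [SampleMetadata("A", "Otemma", "GFS", "pre2000"),
                SampleMetadata("B", "Otemma", "TRIB", "post2000")]
        fam = pd.DataFrame([[0.5, 0.5]], index=["F"], columns=["A", "B"])
        with pytest.warns(UserWarning):
            assert family_enrichment(fam, meta) == []
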