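"""Network inference: Pearson machinery, p-value gate, DPI pruning against a
brute-force oracle, bootstrap likelihood, and full-pipeline invariants."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import metabnet as mn
from metabnet.inference import _dpi_removed, candidate_edges, dpi_prune
from metabnet.matrix import METABOLITE, TRANSCRIPT, OmicsMatrix


# ---------------------------------------------------------------------------
# Pearson machinery
# ---------------------------------------------------------------------------

class TestPearsonWithP:
    def test_perfect_positive(self):
        r, p, n = mn.pearson_with_p([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0) and p == 0.0 and n == 4

    def test_perfect_negative(self):
        r, _, _ = mn.pearson_with_p([1, 2, 3, 4], [8, 6, 4, 2])
        assert r == pytest.approx(-1.0)

    def test_worked_example_r08(self):
        r, p, n = mn.pearson_with_p([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert r == pytest.approx(0.8, abs=1e-12)
        t = 0.8 * np.sqrt(3 / 0.36)
        assert p == pytest.approx(2 * stats.t.sf(t, 3), abs=1e-12)

    def test_closed_form_t_tail_grid(self):
        """p agrees with the closed-form t-tail within 1e-10 over a grid of
        exact sample correlations r in {0,...,0.9}, n in {5,20,100}."""
        rng = np.random.default_rng(0)
        for n in (5, 20, 100):
            x = rng.standard_normal(n)
            e = rng.standard_normal(n)
            zx = (x - x.mean()) / x.std()
            u = e - e.mean()
            u -= (u @ zx) / (zx @ zx) * zx
            u /= u.std()
            for r_target in np.arange(0.0, 1.0, 0.1):
                y = r_target * zx + np.sqrt(1 - r_target**2) * u
                r, p, _ = mn.pearson_with_p(x, y)
                assert r == pytest.approx(r_target, abs=1e-10)
                if r_target > 0:
                    t = r_target * np.sqrt((n - 2) / (1 - r_target**2))
                    assert p == pytest.approx(2 * stats.t.sf(t, n - 2), abs=1e-10)
                else:
                    assert p == pytest.approx(1.0, abs=1e-10)

    def test_agrees_with_scipy_on_random_data(self):
        rng = np.random.default_rng(1)
        for n in (5, 11, 40):
            x, y = rng.standard_normal((2, n))
            r, p, _ = mn.pearson_with_p(x, y)
            ref = stats.pearsonr(x, y)
            assert r == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_missing_handled_pairwise_complete(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, 4.0, 6.0, 8.0, np.nan]
        r, p, n = mn.pearson_with_p(x, y)
        assert n == 3
        ref = stats.pearsonr([1, 2, 4], [2, 4, 8])
        assert r == pytest.approx(ref.statistic)

    @pytest.mark.parametrize(
        "x, y",
        [([1, 2], [3, 4]), ([1, 1, 1, 1], [1, 2, 3, 4])],
    )
    def test_not_computable_marker(self, x, y):
        r, p, _ = mn.pearson_with_p(x, y)
        assert np.isnan(r) and np.isnan(p)


# ---------------------------------------------------------------------------
# Candidate gate
# ---------------------------------------------------------------------------

def _tiny_combined(metab_vals, expr_vals, mids=None, tids=None):
    mids = mids or [f"m{i}" for i in range(len(metab_vals))]
    tids = tids or [f"g{i}" for i in range(len(expr_vals))]
    cols = [f"s{j}" for j in range(len(metab_vals[0]) if metab_vals else len(expr_vals[0]))]
    metab = OmicsMatrix.from_frame(pd.DataFrame(metab_vals, index=mids, columns=cols), METABOLITE)
    expr = OmicsMatrix.from_frame(pd.DataFrame(expr_vals, index=tids, columns=cols), TRANSCRIPT)
    return mn.combine_matrices(metab, expr)


class TestCandidateEdges:
    def test_planted_pair_retained(self, combined_a, gt_strong):
        cands = candidate_edges(combined_a, mn.InferenceConfig(seed=0))
        got = set(zip(cands.mt["metabolite"], cands.mt["transcript"]))
        planted = {(m, t) for m, t, _ in gt_strong.planted_edges()}
        assert len(planted & got) / len(planted) > 0.99
        assert (cands.mt["p"] <= 0.001).all()
        assert (cands.mt["n_pairs"] >= 10).all()

    def test_noise_retention_near_gate_probability(self):
        """Independent noise pairs pass the p = 0.001 gate at about that
        rate: 4000 null pairs at n = 200 retain ~4 edges."""
        rng = np.random.default_rng(12)
        combined = _tiny_combined(
            rng.standard_normal((2, 200)).tolist(), rng.standard_normal((2000, 200)).tolist()
        )
        cands = candidate_edges(combined, mn.InferenceConfig(seed=0))
        assert len(cands.mt) <= stats.binom.ppf(0.9999, 4000, 0.001)

    def test_zero_transcripts_empty_set(self):
        rng = np.random.default_rng(4)
        cols = [f"s{j}" for j in range(20)]
        metab = OmicsMatrix.from_frame(
            pd.DataFrame(rng.standard_normal((2, 20)), index=["m1", "m2"], columns=cols),
            METABOLITE,
        )
        cands = candidate_edges(
            mn.OmicsMatrix(values=metab.values, kinds=metab.kinds), mn.InferenceConfig(seed=0)
        )
        assert cands.mt.empty


# ---------------------------------------------------------------------------
# DPI
# ---------------------------------------------------------------------------

def _dpi_oracle(mt, mm):
    """Explicit enumeration of every (m1, m2, t) triplet."""
    edges = {(m, t): abs(r) for m, t, r in zip(mt["metabolite"], mt["transcript"], mt["r"])}
    removed = set()
    for m1, m2, rmm in zip(mm["m1"], mm["m2"], mm["r"]):
        for (m, t), a in list(edges.items()):
            if m != m1:
                continue
            if (m2, t) not in edges:
                continue
            b = edges[(m2, t)]
            c = abs(rmm)
            if a < b and a < c:
                removed.add((m1, t))
            if b < a and b < c:
                removed.add((m2, t))
    return removed


def _random_instance(rng):
    n_m = rng.integers(2, 11)
    n_t = rng.integers(1, 51)
    mids = [f"m{i}" for i in range(n_m)]
    tids = [f"t{i}" for i in range(n_t)]
    rows = []
    for m in mids:
        for t in tids:
            if rng.random() < 0.3:
                rows.append((m, t, rng.uniform(-1, 1), 1e-4, 50))
    mt = pd.DataFrame(rows, columns=["metabolite", "transcript", "r", "p", "n_pairs"])
    mrows = []
    for i in range(n_m):
        for j in range(i + 1, n_m):
            if rng.random() < 0.5:
                mrows.append((mids[i], mids[j], rng.uniform(-1, 1), 1e-4, 50))
    mm = pd.DataFrame(mrows, columns=["m1", "m2", "r", "p", "n_pairs"])
    return mt, mm


class TestDPI:
    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            mt, mm = _random_instance(rng)
            flags = _dpi_removed(mt, mm)
            got = {(m, t) for m, t, f in zip(mt["metabolite"], mt["transcript"], flags) if f}
            assert got == _dpi_oracle(mt, mm)

    def test_lowest_edge_in_triplet_removed(self):
        mt = pd.DataFrame(
            [("m1", "t", 0.3, 1e-5, 50), ("m2", "t", 0.7, 1e-5, 50)],
            columns=["metabolite", "transcript", "r", "p", "n_pairs"],
        )
        mm = pd.DataFrame([("m1", "m2", 0.8, 1e-5, 50)], columns=["m1", "m2", "r", "p", "n_pairs"])
        flags = _dpi_removed(mt, mm)
        assert list(flags) == [True, False]

    def test_absent_mm_correlation_keeps_both(self):
        mt = pd.DataFrame(
            [("m1", "t", 0.3, 1e-5, 50), ("m2", "t", 0.7, 1e-5, 50)],
            columns=["metabolite", "transcript", "r", "p", "n_pairs"],
        )
        mm = pd.DataFrame(columns=["m1", "m2", "r", "p", "n_pairs"])
        assert not _dpi_removed(mt, mm).any()

    def test_exact_tie_keeps_all(self):
        mt = pd.DataFrame(
            [("m1", "t", 0.5, 1e-5, 50), ("m2", "t", -0.5, 1e-5, 50)],
            columns=["metabolite", "transcript", "r", "p", "n_pairs"],
        )
        mm = pd.DataFrame([("m1", "m2", 0.9, 1e-5, 50)], columns=["m1", "m2", "r", "p", "n_pairs"])
        assert not _dpi_removed(mt, mm).any()

    def test_never_removes_strongest_incident_edge_of_a_metabolite(self):
        """An edge strictly stronger than everything else incident to its
        metabolite (including the auxiliary metabolite-metabolite
        correlations) can never lose a triplet."""
        rng = np.random.default_rng(7)
        for _ in range(30):
            mt, mm = _random_instance(rng)
            if mt.empty:
                continue
            flags = _dpi_removed(mt, mm)
            mm_strength = {}
            for m1, m2, r in zip(mm["m1"], mm["m2"], mm["r"]):
                for m in (m1, m2):
                    mm_strength[m] = max(mm_strength.get(m, 0.0), abs(r))
            strongest = mt.assign(a=mt["r"].abs()).groupby("metabolite")["a"].idxmax()
            for m, idx in strongest.items():
                if mt.loc[idx, "r"] is not None and abs(mt.loc[idx, "r"]) > mm_strength.get(m, 0.0):
                    assert not flags[idx]


# ---------------------------------------------------------------------------
# Bootstrap likelihood
# ---------------------------------------------------------------------------

class TestBootstrap:
    def test_near_collinear_pair_fully_supported(self):
        gt = mn.build_ground_truth(
            n_metabolites=1, targets_per_metabolite=1, beta_range=(3.2, 3.3),
            sigma_m=0.1, n_background=30, neg_fraction=0.0, seed=5,
        )
        ds = mn.simulate_dataset(gt, 50, seed=6)
        combined = mn.combine_matrices(ds.metabolites, ds.transcripts)
        cfg = mn.InferenceConfig(n_bootstraps=20, seed=8)
        cands = dpi_prune(candidate_edges(combined, cfg))
        k = mn.bootstrap_likelihood(combined, cands, cfg)
        planted_t = gt.targets["transcript"].iloc[0]
        row = cands.mt.index[cands.mt["transcript"] == planted_t][0]
        assert k[row] == 20

    def test_b_zero_is_config_error(self):
        with pytest.raises(ValueError, match="n_bootstraps"):
            mn.InferenceConfig(n_bootstraps=0)

    def test_deterministic_given_seed(self, combined_a):
        cfg = mn.InferenceConfig(n_bootstraps=5, seed=77)
        cands = dpi_prune(candidate_edges(combined_a, cfg))
        k1 = mn.bootstrap_likelihood(combined_a, cands, cfg)
        k2 = mn.bootstrap_likelihood(combined_a, cands, cfg)
        np.testing.assert_array_equal(k1, k2)


# ---------------------------------------------------------------------------
# Full inference
# ---------------------------------------------------------------------------

class TestInferNetwork:
    def test_recovers_planted_edges(self, net_a, gt_strong):
        precision, recall = mn.edge_recovery(net_a, gt_strong)
        assert recall >= 0.9 and precision >= 0.9

    def test_dpi_removed_but_bootstrapped_edge_kept_with_k_over_b(self, combined_coupled):
        cfg = mn.InferenceConfig(n_bootstraps=25, seed=9)
        net = mn.infer_network(combined_coupled, cfg)
        recovered = net.edges[~net.edges["dpi_survivor"]]
        assert len(recovered) > 0
        ks = recovered["likelihood"] * cfg.n_bootstraps
        np.testing.assert_allclose(ks, np.round(ks))
        assert (recovered["likelihood"] >= 1 / cfg.n_bootstraps).all()

    def test_structure_invariant_to_permutations(self, sim_a):
        cfg = mn.InferenceConfig(n_bootstraps=1, seed=3)
        combined = mn.combine_matrices(sim_a.metabolites, sim_a.transcripts)
        base = mn.infer_network(combined, cfg)
        rng = np.random.default_rng(0)
        scrambled = mn.combine_matrices(
            sim_a.metabolites.subset(samples=rng.permutation(sim_a.metabolites.sample_ids)),
            sim_a.transcripts.subset(
                features=rng.permutation(sim_a.transcripts.feature_ids)
            ),
        )
        other = mn.infer_network(scrambled, cfg)

        def sorted_edges(net):
            return net.edges.sort_values(["metabolite", "transcript"]).reset_index(drop=True)

        e1, e2 = sorted_edges(base), sorted_edges(other)
        assert list(zip(e1["metabolite"], e1["transcript"])) == list(
            zip(e2["metabolite"], e2["transcript"])
        )
        # r recomputed under permuted summation order: equal up to round-off
        np.testing.assert_allclose(e1["r"], e2["r"], atol=1e-9)

    def test_bit_identical_given_seed(self, combined_a):
        cfg = mn.InferenceConfig(n_bootstraps=10, seed=123)
        n1 = mn.infer_network(combined_a, cfg)
        n2 = mn.infer_network(combined_a, cfg)
        assert n1.equals(n2)

    def test_pure_noise_yields_near_gate_edge_count(self):
        rng = np.random.default_rng(31)
        combined = _tiny_combined(
            rng.standard_normal((5, 200)).tolist(), rng.standard_normal((800, 200)).tolist()
        )
        net = mn.infer_network(combined, mn.InferenceConfig(n_bootstraps=10, seed=2))
        # 4000 null pairs at gate 0.001
        assert net.n_edges <= stats.binom.ppf(0.9999, 4000, 0.001)
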