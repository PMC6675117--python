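"""Pairwise correlation, permutation eFDR, and the significance screen."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from methiso.correlate import (EFDRResult, THRESHOLD_GRID, empirical_fdr,
                               pair_correlations, rowwise_pearson,
                               select_variable_probes, significant_pairs)


def frame(arr, prefix, samples):
    return pd.DataFrame(arr, index=[f"{prefix}{i}" for i in range(len(arr))],
                        columns=samples)


def pair_table(n):
    return pd.DataFrame({"gene_id": [f"g{i}" for i in range(n)],
                         "transcript_id": [f"t{i}" for i in range(n)],
                         "probe_id": [f"p{i}" for i in range(n)]})


class TestPairCorrelations:
    def test_affine_coupling_gives_unit_r(self):
        samples = [f"S{i}" for i in range(30)]
        b = np.linspace(0.1, 0.9, 30)
        usage = frame([0.1 + 0.5 * b], "t", samples)
        beta = frame([b], "p", samples)
        rec = pair_correlations(usage, beta, pair_table(1), min_n=5)
        assert rec.r.iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_constant_beta_pair_omitted(self):
        samples = [f"S{i}" for i in range(10)]
        usage = frame([np.linspace(0, 1, 10)], "t", samples)
        beta = frame([np.full(10, 0.4)], "p", samples)
        assert len(pair_correlations(usage, beta, pair_table(1), min_n=5)) == 0

    def test_five_sample_closed_form(self):
        x = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        y = np.array([0.9, 0.7, 0.6, 0.4, 0.2])
        samples = list("abcde")
        rec = pair_correlations(frame([y], "t", samples), frame([x], "p", samples),
                                pair_table(1), min_n=3)
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        want = cov / (x.std() * y.std())
        assert rec.r.iloc[0] == pytest.approx(want, abs=1e-12)

    @pytest.mark.parametrize("method", ["pearson", "spearman"])
    def test_matches_scipy_on_random_vectors(self, method):
        rng = np.random.default_rng(0)
        samples = [f"S{i}" for i in range(12)]
        U = rng.random((200, 12))
        B = rng.random((200, 12))
        rec = pair_correlations(frame(U, "t", samples), frame(B, "p", samples),
                                pair_table(200), method=method, min_n=5)
        f = stats.pearsonr if method == "pearson" else stats.spearmanr
        for row in rec.itertuples(index=False):
            i = int(row.transcript_id[1:])
            want = f(U[i], B[i])[0]
            assert row.r == pytest.approx(want, abs=1e-12)

    def test_pairwise_complete_with_missing(self):
        samples = [f"S{i}" for i in range(8)]
        u = np.array([0.1, 0.4, np.nan, 0.5, 0.2, 0.9, 0.3, 0.6])
        b = np.array([0.2, 0.5, 0.7, np.nan, 0.1, 0.8, 0.4, 0.55])
        rec = pair_correlations(frame([u], "t", samples), frame([b], "p", samples),
                                pair_table(1), min_n=3)
        m = np.isfinite(u) & np.isfinite(b)
        want = stats.pearsonr(u[m], b[m])[0]
        assert rec.n_used.iloc[0] == m.sum()
        assert rec.r.iloc[0] == pytest.approx(want, abs=1e-12)

    def test_no_overlapping_samples_raises(self):
        usage = frame([[0.1, 0.2]], "t", ["A", "B"])
        beta = frame([[0.1, 0.2]], "p", ["C", "D"])
        with pytest.raises(ValueError, match="overlap"):
            pair_correlations(usage, beta, pair_table(1))


class TestEmpiricalFdr:
    def test_deterministic_couplings_zero_efdr_at_high_threshold(self):
        rng = np.random.default_rng(1)
        samples = [f"S{i}" for i in range(20)]
        B = rng.random((10, 20))
        U = 0.2 + 0.6 * B  # |r| = 1 for every pair
        res = empirical_fdr(frame(U, "t", samples), frame(B, "p", samples),
                            pair_table(10), B=20, seed=0, min_n=5)
        assert res.efdr[res.thresholds == 0.9][0] == 0.0
        assert res.r_star is not None

    def test_pure_noise_efdr_near_one_at_low_threshold(self):
        rng = np.random.default_rng(2)
        vals = []
        for rep in range(50):
            samples = [f"S{i}" for i in range(40)]
            U = rng.random((40, 40))
            B = rng.random((40, 40))
            res = empirical_fdr(frame(U, "t", samples), frame(B, "p", samples),
                                pair_table(40), B=20, seed=rep, min_n=5)
            vals.append(res.efdr[res.thresholds == 0.05][0])
        assert np.mean(vals) > 0.8

    def test_exhaustive_permutations_match_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        n = 5
        samples = [f"S{i}" for i in range(n)]
        U = rng.random((3, n))
        B = rng.random((3, n))
        perms = [list(p) for p in itertools.permutations(range(n))]
        res = empirical_fdr(frame(U, "t", samples), frame(B, "p", samples),
                            pair_table(3), seed=0, min_n=2, perm_list=perms)
        # independent oracle: per-permutation scipy correlations, then the
        # capped ratio with a running minimum over the threshold grid
        obs = [abs(stats.pearsonr(U[i], B[i])[0]) for i in range(3)]
        null = [abs(stats.pearsonr(U[i], B[i][list(p)])[0])
                for p in perms for i in range(3)]
        running = math.inf
        for j, t in enumerate(THRESHOLD_GRID):
            o = sum(v >= t for v in obs)
            nl = sum(v >= t for v in null) / len(perms)
            raw = min(nl / o, 1.0) if o else 0.0
            running = min(running, raw)
            assert res.efdr[j] == pytest.approx(running, abs=1e-12)

    def test_efdr_monotone_nonincreasing(self):
        rng = np.random.default_rng(4)
        samples = [f"S{i}" for i in range(15)]
        res = empirical_fdr(frame(rng.random((20, 15)), "t", samples),
                            frame(rng.random((20, 15)), "p", samples),
                            pair_table(20), B=10, seed=1, min_n=5)
        assert (np.diff(res.efdr) <= 1e-15).all()


class TestVariableProbes:
    def test_top_quartile_by_sd(self):
        rng = np.random.default_rng(5)
        rows = [rng.normal(0.5, 0.01 * (i + 1), 50) for i in range(8)]
        beta = frame(np.clip(rows, 0, 1), "cg", [f"S{i}" for i in range(50)])
        assert select_variable_probes(beta) == {"cg6", "cg7"}  # ceil(0.25*8)=2

    def test_tie_break_lexicographic(self):
        beta = frame(np.tile(np.linspace(0, 1, 10), (8, 1)), "cg",
                     [f"S{i}" for i in range(10)])
        assert select_variable_probes(beta) == {"cg0", "cg1"}

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(6)
        beta = frame(rng.random((37, 25)), "cg", [f"S{i}" for i in range(25)])
        got = select_variable_probes(beta, q=0.25)
        sd = beta.std(axis=1, ddof=1)
        order = sorted(beta.index, key=lambda p: (-sd[p], p))
        assert got == set(order[:math.ceil(0.25 * 37)])


class TestSignificantPairs:
    def _efdr(self, r_star):
        g = THRESHOLD_GRID
        return EFDRResult(g, np.ones_like(g), r_star, 10, 0, 5,
                          np.zeros_like(g), np.zeros_like(g))

    def _records(self, rs):
        return pd.DataFrame({"gene_id": [f"g{i}" for i in range(len(rs))],
                             "transcript_id": [f"t{i}" for i in range(len(rs))],
                             "probe_id": [f"p{i}" for i in range(len(rs))],
                             "r": rs, "n_used": 50, "method": "pearson"})

    def test_ineligible_cohort(self):
        recs = self._records([0.9, -0.8])
        out, verdict, summary = significant_pairs(recs, self._efdr(0.45),
                                                  {"p0", "p1"})
        assert verdict == "INELIGIBLE" and out.empty and summary["n_pair"] == 0

    def test_strict_threshold_and_variable_set(self):
        recs = self._records([0.31, 0.30, -0.5])
        out, verdict, _ = significant_pairs(recs, self._efdr(0.2),
                                            {"p0", "p1"})  # p2 not variable
        assert verdict == "ELIGIBLE"
        assert set(out.probe_id) == {"p0"}  # 0.30 dropped (strict >), p2 filtered

    def test_planted_pairs_recovered(self, small_cohort):
        from methiso.genome_model import intragenic_pairs
        from methiso.preprocess import compute_usage
        cfg, ann, beta, tpm, meta, truth = small_cohort
        tumors = meta.index[meta.group == "tumor"]
        usage = compute_usage(tpm, ann.genes)
        pairs = intragenic_pairs(ann.genes, ann.probes)
        recs = pair_correlations(usage[tumors], beta[tumors], pairs, min_n=30)
        efdr = empirical_fdr(usage[tumors], beta[tumors], pairs, B=50, seed=1,
                             min_n=30)
        variable = select_variable_probes(beta[tumors])
        sig, verdict, _ = significant_pairs(recs, efdr, variable)
        assert verdict == "ELIGIBLE"
        planted = set(zip(truth.planted_pairs.transcript_id,
                          truth.planted_pairs.probe_id))
        got = set(zip(sig.transcript_id, sig.probe_id))
        # planted population |r| = 0.5 at n = 80: expect nearly all recovered
        assert len(planted & got) >= 0.9 * len(planted)


class TestCorrelationProperties:
    """Randomized invariants of the row-wise correlation kernel."""

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_rowwise_matches_scipy_and_is_shift_scale_invariant(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 20))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        r, used = rowwise_pearson(x[None, :], y[None, :])
        assert used[0] == n
        assert r[0] == pytest.approx(stats.pearsonr(x, y)[0], abs=1e-10)
        # invariance under positive affine maps of either argument
        r2, _ = rowwise_pearson((2.5 * x + 7)[None, :], (0.3 * y - 1)[None, :])
        assert r2[0] == pytest.approx(r[0], abs=1e-9)
        # antisymmetry under negation
        r3, _ = rowwise_pearson((-x)[None, :], y[None, :])
        assert r3[0] == pytest.approx(-r[0], abs=1e-9)
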