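"""TMM normalization, moderated-t differential expression, volcano
classification, BH-FDR and pseudobulk CPM."""

import math

import numpy as np
import pandas as pd
import pytest

from cernaforge import diffexp


def _tmm_oracle(counts: pd.DataFrame, m_trim=0.30, a_trim=0.05) -> pd.Series:
    """Straight-line re-implementation of the trimmed mean of M-values,
    written independently of the package (plain loops, no shared helpers)."""
    lib = {s: float(counts[s].sum()) for s in counts.columns}
    uq = {s: float(np.quantile(counts[s] / lib[s], 0.75)) for s in counts.columns}
    mean_uq = sum(uq.values()) / len(uq)
    ref = min(counts.columns, key=lambda s: abs(uq[s] - mean_uq))
    factors = {}
    for s in counts.columns:
        ms, as_, ws = [], [], []
        for f in counts.index:
            yk, yr = float(counts.loc[f, s]), float(counts.loc[f, ref])
            if yk <= 0 or yr <= 0:
                continue
            pk, pr = yk / lib[s], yr / lib[ref]
            ms.append(math.log2(pk / pr))
            as_.append(0.5 * math.log2(pk * pr))
            ws.append(1.0 / ((1.0 - pk) / pk + (1.0 - pr) / pr))
        n = len(ms)
        order_m = sorted(range(n), key=lambda i: ms[i])
        order_a = sorted(range(n), key=lambda i: as_[i])
        rank_m = {i: r + 1 for r, i in enumerate(order_m)}
        rank_a = {i: r + 1 for r, i in enumerate(order_a)}
        lo_m = math.floor(n * m_trim) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * a_trim) + 1
        hi_a = n + 1 - lo_a
        num = den = 0.0
        for i in range(n):
            if lo_m <= rank_m[i] <= hi_m and lo_a <= rank_a[i] <= hi_a:
                num += ws[i] * ms[i]
                den += ws[i]
        factors[s] = 2.0 ** (num / den) if den else 1.0
    logs = [math.log(v) for v in factors.values()]
    gm = math.exp(sum(logs) / len(logs))
    return pd.Series({s: v / gm for s, v in factors.items()})


class TestTMM:
    def test_identical_columns_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 5, 40], "b": [10, 20, 5, 40]})
        res = diffexp.tmm_factors(counts)
        assert np.allclose(res.factors, 1.0)

    def test_pure_scaling_gives_equal_normalized_columns(self, rng):
        col = rng.integers(10, 400, 200)
        counts = pd.DataFrame({"a": col, "b": 2 * col})
        norm = diffexp.tmm_normalize(counts)
        assert np.allclose(norm["a"], norm["b"], rtol=1e-8)

    def test_scale_invariance_of_normalized_values(self, rng):
        counts = pd.DataFrame(rng.negative_binomial(5, 0.05, (300, 4)) + 1,
                              columns=list("abcd"))
        norm1 = diffexp.tmm_normalize(counts)
        scaled = counts.copy()
        scaled["c"] = scaled["c"] * 3
        norm2 = diffexp.tmm_normalize(scaled)
        assert np.allclose(norm1.to_numpy(), norm2.to_numpy(), rtol=1e-8)

    def test_matches_independent_reimplementation(self, rng):
        counts = pd.DataFrame(rng.negative_binomial(4, 0.02, (250, 5)),
                              columns=list("abcde"),
                              index=[f"f{i}" for i in range(250)])
        counts += (counts.sum(axis=1) == 0).astype(int).to_numpy()[:, None]
        res = diffexp.tmm_factors(counts)
        oracle = _tmm_oracle(counts)
        assert np.allclose(res.factors[oracle.index], oracle, atol=1e-6)

    def test_all_zero_sample_errors(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError, match="all-zero"):
            diffexp.tmm_factors(counts)

    def test_geometric_mean_is_one(self, rng):
        counts = pd.DataFrame(rng.integers(1, 500, (100, 6)))
        res = diffexp.tmm_factors(counts)
        assert np.exp(np.log(res.factors).mean()) == pytest.approx(1.0, abs=1e-12)


def _design(na, nb):
    return pd.DataFrame(dict(
        sample=[f"a{i}" for i in range(na)] + [f"b{i}" for i in range(nb)],
        group=["A"] * na + ["B"] * nb))


class TestDETest:
    def test_constant_features_give_p_one_and_zero_lfc(self):
        design = _design(6, 6)
        x = pd.DataFrame(np.full((5, 12), 3.0), columns=design["sample"],
                         index=[f"f{i}" for i in range(5)])
        de = diffexp.de_test(x, design, ("B", "A"))
        assert np.allclose(de["log2fc"], 0.0)
        assert np.allclose(de["p_raw"], 1.0)

    def test_planted_effect_detected_as_both(self, rng):
        design = _design(12, 12)
        x = pd.DataFrame(rng.normal(5, 0.3, (50, 24)), columns=design["sample"],
                         index=[f"f{i}" for i in range(50)])
        x.loc["f0", list(design.loc[design.group == "B", "sample"])] += 2.0
        de = diffexp.de_test(x, design, ("B", "A")).set_index("feature_id")
        assert de.loc["f0", "volcano_class"] == "both"
        assert de.loc["f0", "log2fc"] == pytest.approx(2.0, abs=0.4)

    def test_contrast_swap_negates_lfc_preserves_p(self, rng):
        design = _design(5, 7)
        x = pd.DataFrame(rng.normal(0, 1, (40, 12)), columns=design["sample"],
                         index=[f"f{i}" for i in range(40)])
        d1 = diffexp.de_test(x, design, ("B", "A"))
        d2 = diffexp.de_test(x, design, ("A", "B"))
        assert np.allclose(d1["log2fc"], -d2["log2fc"])
        assert np.allclose(d1["p_raw"], d2["p_raw"])

    def test_null_type_one_error_near_nominal(self, rng):
        design = _design(12, 12)
        hits = tot = 0
        for _ in range(10):
            x = pd.DataFrame(rng.normal(5, 1, (1000, 24)),
                             columns=design["sample"],
                             index=[f"f{i}" for i in range(1000)])
            de = diffexp.de_test(x, design, ("B", "A"))
            hits += int((de["p_raw"] < 0.05).sum())
            tot += len(de)
        rate = hits / tot
        ci = 2.576 * math.sqrt(0.05 * 0.95 / tot)
        assert abs(rate - 0.05) < ci + 0.002

    def test_welch_variant_runs(self, rng):
        design = _design(6, 6)
        x = pd.DataFrame(rng.normal(0, 1, (20, 12)), columns=design["sample"],
                         index=[f"f{i}" for i in range(20)])
        de = diffexp.de_test(x, design, ("B", "A"), stat="welch")
        assert ((de["p_raw"] > 0) & (de["p_raw"] <= 1)).all()

    def test_small_group_errors(self):
        design = pd.DataFrame(dict(sample=["a0", "b0", "b1"],
                                   group=["A", "B", "B"]))
        x = pd.DataFrame(np.ones((3, 3)), columns=design["sample"])
        with pytest.raises(ValueError, match="fewer than 2"):
            diffexp.de_test(x, design, ("B", "A"))


class TestVolcano:
    @pytest.mark.parametrize("lfc,p,expected", [
        (0.60, 0.01, "both"),
        (0.58, 0.049, "both"),      # FC boundary inclusive, P strict
        (0.58, 0.05, "fc_only"),    # P boundary is strict
        (0.57, 0.01, "p_only"),
        (-0.60, 0.2, "fc_only"),
        (0.10, 0.5, "ns"),
    ])
    def test_threshold_policy(self, lfc, p, expected):
        de = pd.DataFrame(dict(feature_id=["f"], log2fc=[lfc], p_raw=[p]))
        out = diffexp.classify_volcano(de)
        assert out.iloc[0].volcano_class == expected

    def test_counts_equal_bruteforce(self, rng):
        de = pd.DataFrame(dict(
            feature_id=[f"f{i}" for i in range(500)],
            log2fc=rng.normal(0, 1, 500),
            p_raw=rng.uniform(1e-6, 1, 500)))
        out = diffexp.classify_volcano(de)
        counts = diffexp.volcano_counts(out)
        brute = {"both": 0, "fc_only": 0, "p_only": 0, "ns": 0}
        for row in de.itertuples():
            fc = abs(row.log2fc) >= 0.58
            pp = row.p_raw < 0.05
            brute["both" if fc and pp else "fc_only" if fc
                  else "p_only" if pp else "ns"] += 1
        assert dict(counts) == brute


class TestBH:
    def test_hand_stepup_example(self):
        out = diffexp.bh_fdr([0.01, 0.02, 0.03])
        assert np.allclose(out, [0.03, 0.03, 0.03])

    def test_single_value_unchanged(self):
        assert diffexp.bh_fdr([0.04])[0] == pytest.approx(0.04)

    def test_matches_textbook_implementation(self, rng):
        p = rng.uniform(1e-8, 1, 97)
        out = diffexp.bh_fdr(p)
        # textbook step-up: sort, multiply by m/i, enforce monotone from the top
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            adj[i] = running
        assert np.allclose(out, adj, atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            diffexp.bh_fdr([0.5, 0.0])
        with pytest.raises(ValueError):
            diffexp.bh_fdr([1.5])


class TestPseudobulk:
    def test_forced_arithmetic(self):
        counts = pd.DataFrame([[3, 1]], columns=["gene1", "gene2"], index=["c1"])
        cpm, log2cpm = diffexp.pseudobulk_cpm(counts, ["EC"], ["d1"])
        assert cpm.loc[("d1", "EC"), "gene1"] == pytest.approx(750000.0)
        assert cpm.loc[("d1", "EC"), "gene2"] == pytest.approx(250000.0)
        assert log2cpm.loc[("d1", "EC"), "gene1"] == pytest.approx(math.log2(750001))

    def test_duplicate_cells_scale_invariance(self):
        one = pd.DataFrame([[4, 6]], columns=["g1", "g2"], index=["c1"])
        two = pd.DataFrame([[4, 6], [4, 6]], columns=["g1", "g2"],
                           index=["c1", "c2"])
        cpm1, _ = diffexp.pseudobulk_cpm(one, ["EC"], ["d"])
        cpm2, _ = diffexp.pseudobulk_cpm(two, ["EC", "EC"], ["d", "d"])
        pd.testing.assert_frame_equal(cpm1, cpm2)

    def test_matches_dense_bruteforce(self, rng):
        n_cells, n_genes = 50, 12
        counts = pd.DataFrame(
            rng.integers(0, 4, (n_cells, n_genes)) * (rng.random((n_cells, n_genes)) < 0.3),
            columns=[f"g{j}" for j in range(n_genes)],
            index=[f"c{i}" for i in range(n_cells)])
        types = list(rng.choice(["EC", "CM", "FB"], n_cells))
        donors = list(rng.choice(["d1", "d2"], n_cells))
        cpm, _ = diffexp.pseudobulk_cpm(counts, types, donors)
        for (donor, ctype) in cpm.index:
            cells = [i for i, (t, d) in enumerate(zip(types, donors))
                     if t == ctype and d == donor]
            sums = counts.iloc[cells].sum(axis=0)
            expected = sums / sums.sum() * 1e6
            assert np.allclose(cpm.loc[(donor, ctype)], expected)
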