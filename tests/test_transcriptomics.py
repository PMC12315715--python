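"""QC, filtering, CPM, signed-KS differential expression, BH, exon usage."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import hypercell as hc


def frame(data, genes=None, cells=None):
    data = np.asarray(data)
    genes = genes or [f"g{i}" for i in range(data.shape[0])]
    cells = cells or [f"c{i}" for i in range(data.shape[1])]
    return pd.DataFrame(data, index=genes, columns=cells)


class TestQcMetrics:
    def test_mt_fraction_and_class(self):
        counts = frame([[26], [74]], genes=["MT-CO1", "GAPDH"])
        qc = hc.qc_metrics(counts)
        assert qc["total_reads"].iloc[0] == 100
        assert qc["mt_fraction"].iloc[0] == pytest.approx(0.26)
        assert qc["mt_class"].iloc[0] == "MT-high"  # 0.26 > 0.25

    def test_no_mt_genes_is_mt_low(self):
        qc = hc.qc_metrics(frame([[10], [5]], genes=["A", "B"]))
        assert qc["mt_fraction"].iloc[0] == 0.0
        assert qc["mt_class"].iloc[0] == "MT-low"

    def test_boundary_exactly_25_percent_is_low(self):
        qc = hc.qc_metrics(frame([[25], [75]], genes=["MT-ND1", "A"]))
        assert qc["mt_class"].iloc[0] == "MT-low"

    def test_ribo_fraction_by_prefix(self):
        counts = frame([[10], [30], [60]], genes=["RPS6", "RPL13", "ACTB"])
        qc = hc.qc_metrics(counts)
        assert qc["ribo_fraction"].iloc[0] == pytest.approx(0.4)

    def test_zero_total_cell_flagged(self):
        with pytest.warns(UserWarning, match="zero total"):
            qc = hc.qc_metrics(frame([[0, 5]], genes=["A"]))
        assert np.isnan(qc["mt_fraction"].iloc[0])
        assert qc["mt_class"].iloc[0] == "undefined"


class TestFilterGenes:
    def test_boundary_at_min_cells(self):
        data = np.zeros((2, 12), dtype=int)
        data[0, :9] = 1  # 9 cells -> dropped
        data[1, :10] = 1  # 10 cells -> kept
        kept = hc.filter_genes(frame(data), min_cells=10)
        assert list(kept.index) == ["g1"]

    def test_min_cells_one_drops_only_all_zero(self):
        data = np.array([[0, 0, 0], [1, 0, 0]])
        kept = hc.filter_genes(frame(data), min_cells=1)
        assert list(kept.index) == ["g1"]

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(12)
        data = rng.poisson(0.4, size=(60, 25))
        counts = frame(data)
        kept = hc.filter_genes(counts, min_cells=10)
        expected = [
            g for i, g in enumerate(counts.index) if int((data[i] > 0).sum()) >= 10
        ]
        assert list(kept.index) == expected


class TestCpm:
    def test_columns_sum_to_one_million(self, sim_counts):
        cpm = hc.cpm_normalize(sim_counts["genes"])
        assert np.allclose(cpm.sum(axis=0), 1e6)

    def test_two_gene_cell(self):
        cpm = hc.cpm_normalize(frame([[1], [3]]))
        assert cpm.iloc[:, 0].tolist() == [250000.0, 750000.0]

    def test_zero_total_cell_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="zero-total"):
            cpm = hc.cpm_normalize(frame([[1, 0], [1, 0]]))
        assert cpm.shape[1] == 1


def ks_enumeration_oracle(a, b):
    """Exact permutation distribution of the two-sample KS D by explicit
    enumeration, computing D as the max ECDF gap over a value sweep."""

    def d_stat(x, y):
        best = 0.0
        for v in np.concatenate([x, y]):
            gap = abs((x <= v).mean() - (y <= v).mean())
            best = max(best, gap)
        return best

    observed = d_stat(np.asarray(a, float), np.asarray(b, float))
    pooled = np.concatenate([a, b]).astype(float)
    n = len(a)
    hits = total = 0
    for comb in itertools.combinations(range(len(pooled)), n):
        sel = np.zeros(len(pooled), dtype=bool)
        sel[list(comb)] = True
        total += 1
        if d_stat(pooled[sel], pooled[~sel]) >= observed - 1e-12:
            hits += 1
    return observed, hits / total


class TestSignedKsDe:
    def de(self, a_vals, b_vals, **kw):
        a_vals, b_vals = np.atleast_2d(a_vals), np.atleast_2d(b_vals)
        data = np.hstack([a_vals, b_vals])
        cells_a = [f"a{i}" for i in range(a_vals.shape[1])]
        cells_b = [f"b{i}" for i in range(b_vals.shape[1])]
        cpm = frame(data, cells=cells_a + cells_b)
        return hc.signed_ks_de(cpm, cells_a, cells_b, **kw)

    def test_identical_groups_null(self):
        res = self.de([[1, 2, 3, 4]], [[1, 2, 3, 4]], median_filter=False)
        assert res["signed_ks"].iloc[0] == 0.0
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_fully_separated_small_groups(self):
        res = self.de([[1, 2, 3]], [[4, 5, 6]], median_filter=False)
        assert res["signed_ks"].iloc[0] == pytest.approx(-1.0)  # mean_a < mean_b
        assert res["p"].iloc[0] == pytest.approx(2 / 20)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_p_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 40, size=5).astype(float)
        b = rng.integers(0, 40, size=6).astype(float)
        res = self.de([a], [b], median_filter=False)
        d_expected, p_expected = ks_enumeration_oracle(a, b)
        assert abs(res["signed_ks"].iloc[0]) == pytest.approx(d_expected)
        assert res["p"].iloc[0] == pytest.approx(p_expected)

    def test_zero_median_gene_filtered(self):
        res = self.de([[0, 0, 0, 6]], [[3, 4, 5, 6]])
        assert bool(res["filtered"].iloc[0])
        assert res["filter_reason"].iloc[0] == "zero_median"
        assert np.isnan(res["p"].iloc[0])

    def test_log2fc_with_pseudocount(self):
        res = self.de([[3, 3, 3]], [[1, 1, 1]], median_filter=False)
        assert res["log2_fc"].iloc[0] == pytest.approx(1.0)  # (3+1)/(1+1)

    def test_sign_by_median_option(self):
        a = [[0.0, 0.0, 100.0]]
        b = [[2.0, 2.0, 2.0]]
        by_mean = self.de(a, b, median_filter=False, sign_by="mean")
        by_median = self.de(a, b, median_filter=False, sign_by="median")
        assert by_mean["signed_ks"].iloc[0] > 0  # mean 33.3 vs 2
        assert by_median["signed_ks"].iloc[0] < 0  # median 0 vs 2

    def test_overlapping_groups_rejected(self):
        cpm = frame(np.ones((1, 6)))
        with pytest.raises(ValueError, match="disjoint"):
            hc.signed_ks_de(cpm, ["c0", "c1", "c2"], ["c2", "c3", "c4"])

    def test_q_at_least_p(self, sim_counts):
        cpm = hc.cpm_normalize(sim_counts["genes"])
        cells = list(cpm.columns)
        res = hc.signed_ks_de(cpm, cells[:20], cells[20:40])
        ok = res.dropna(subset=["p"])
        assert (ok["q"] >= ok["p"] - 1e-12).all()


class TestBhAdjust:
    def test_single_p(self):
        assert hc.bh_adjust(np.array([0.04]))[0] == pytest.approx(0.04)

    def test_hand_computed_step_up(self):
        q = hc.bh_adjust(np.array([0.01, 0.02, 0.03]))
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert np.allclose(hc.bh_adjust(np.ones(5)), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            hc.bh_adjust(np.array([0.5, 1.2]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        ps=st.lists(st.floats(min_value=0.001, max_value=1.0), min_size=2, max_size=20),
        idx=st.integers(min_value=0, max_value=19),
    )
    def test_shrinking_a_p_never_loses_discoveries(self, ps, idx):
        p = np.array(ps)
        idx %= len(p)
        n_before = int((hc.bh_adjust(p) <= 0.1).sum())
        p2 = p.copy()
        p2[idx] /= 2
        n_after = int((hc.bh_adjust(p2) <= 0.1).sum())
        assert n_after >= n_before


class TestExonUsage:
    def test_single_exon_gene_usage_one(self):
        usage = hc.exon_usage(frame([[7, 0]], genes=["G:1"]))
        assert usage.iloc[0, 0] == pytest.approx(1.0)
        assert np.isnan(usage.iloc[0, 1])

    def test_two_exon_fractions(self):
        usage = hc.exon_usage(frame([[2], [6]], genes=["G:1", "G:2"]))
        assert usage.iloc[:, 0].tolist() == [0.25, 0.75]

    def test_usage_sums_to_one_over_expressing_cells(self, sim_counts):
        usage = hc.exon_usage(sim_counts["exons"])
        genes = [hc.parse_exon_key(k)[0] for k in usage.index]
        sums = usage.groupby(genes).sum(min_count=1)
        expressed = ~usage.groupby(genes).first().isna()
        assert np.allclose(sums.to_numpy()[expressed.to_numpy()], 1.0)

    @pytest.mark.parametrize("bad", ["no-colon", "G:", "G:x", "G:0", ":3"])
    def test_malformed_keys_rejected(self, bad):
        with pytest.raises(ValueError, match="exon key|malformed"):
            hc.parse_exon_key(bad)

    def test_key_with_colon_in_gene_id(self):
        assert hc.parse_exon_key("ENSG:0001:12") == ("ENSG:0001", 12)


class TestNullCalibration:
    def test_type_one_error_rate_on_null_nb_genes(self):
        """Fraction of null genes at p < 0.05 stays near nominal."""
        rng = np.random.default_rng(77)
        feat = rng.uniform(0, 1, 100)
        spec = hc.CountsSimSpec(n_cells=100, n_genes=500, seed=55)
        gene_df, _, _ = hc.simulate_counts(spec, feat)
        gene_df = gene_df.loc[[g for g in gene_df.index if not g.startswith("MT-")]]
        cpm = hc.cpm_normalize(gene_df)
        cells = list(cpm.columns)
        res = hc.signed_ks_de(cpm, cells[:50], cells[50:], median_filter=True)
        tested = res.dropna(subset=["p"])
        frac = float((tested["p"] < 0.05).mean())
        assert 0.02 <= frac <= 0.09
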