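"""Codon-usage statistics against hand computations and independent oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from thermofungi import codon_usage as cu
from thermofungi.formats_io import SequenceSet


# --- independent spreadsheet-style ENC oracle (straight from the formula) ---

def enc_oracle(counts: dict[str, int]) -> float:
    per_aa = {}
    for aa, codons in cu.AA_TO_CODONS.items():
        ns = [counts.get(c, 0) for c in codons]
        n = sum(ns)
        if len(codons) == 1 or n < 2:
            continue
        s2 = sum((x / n) ** 2 for x in ns)
        per_aa[aa] = (n * s2 - 1) / (n - 1)
    means = {}
    for size, aas in cu.DEGENERACY_CLASSES.items():
        vals = [per_aa[a] for a in aas if a in per_aa]
        if vals:
            means[size] = sum(vals) / len(vals)
    if 3 not in means and 2 in means and 4 in means:
        means[3] = (means[2] + means[4]) / 2
    if any(s not in means or means[s] <= 0 for s in (2, 3, 4, 6)):
        return math.nan
    raw = 2 + 9 / means[2] + 1 / means[3] + 5 / means[4] + 3 / means[6]
    return min(raw, 61.0)


class TestCountCodons:
    def test_terminal_stop_trimmed(self):
        cc = cu.count_codons("ATGGCGGCCTAA")
        assert cc.counts == {"ATG": 1, "GCG": 1, "GCC": 1}
        assert cc.stop_count == 1
        assert cc.status == "ok"

    def test_internal_stop_flagged(self):
        assert cu.count_codons("ATGTAAGCG").status == "internal_stop"

    def test_bad_length_flagged(self):
        assert cu.count_codons("ATGGC").status == "bad_length"

    def test_codons_with_n_skipped(self):
        cc = cu.count_codons("ATGANGGCC")
        assert cc.skipped_codons == 1
        assert cc.counts == {"ATG": 1, "GCC": 1}


class TestGc3:
    @pytest.mark.parametrize(
        "codons, expected_gc3, expected_gc3s",
        [
            ({"GCG": 1, "GCC": 1}, 1.0, 1.0),
            ({"GCA": 1, "GCT": 1}, 0.0, 0.0),
            # ATG excluded from the synonymous version only
            ({"ATG": 1, "AAA": 1, "GCG": 1}, 2 / 3, 1 / 2),
        ],
    )
    def test_hand_counts(self, codons, expected_gc3, expected_gc3s):
        cc = cu.CodonCounts(counts=codons)
        assert cu.gc3(cc) == pytest.approx(expected_gc3)
        assert cu.gc3s(cc) == pytest.approx(expected_gc3s)

    def test_no_sense_codons_missing(self):
        assert math.isnan(cu.gc3(cu.CodonCounts()))


class TestEnc:
    def test_uniform_usage_clamps_to_61(self):
        assert cu.enc(cu.uniform_codon_counts(100_000)) == 61.0

    def test_single_codon_per_aa_is_20(self):
        assert cu.enc(cu.single_codon_counts(100_000)) == pytest.approx(20.0)

    def test_two_fold_family_f_hat_hand_value(self):
        # counts (3,1) in a two-fold family: F = (4*(0.5625+0.0625)-1)/3
        cc = cu.CodonCounts(counts={"TTT": 3, "TTC": 1})
        comp = cu.enc_components(cc)
        assert comp.f_hat["F"] == pytest.approx(0.5)

    def test_scale_invariance_in_the_large_count_limit(self, rng):
        """Wright's estimator depends on codon proportions up to a finite-n
        correction of order 1/n, so scaling all counts leaves ENC unchanged
        asymptotically (and nearly so at realistic depths)."""
        counts = {c: int(rng.integers(1, 30)) * 100 for c in cu.SENSE_CODONS}
        a = cu.enc(cu.CodonCounts(counts=counts))
        b = cu.enc(cu.CodonCounts(counts={c: 7 * n for c, n in counts.items()}))
        assert a == pytest.approx(b, abs=0.05)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_independent_oracle(self, seed):
        """ENC agrees with a second, direct implementation of the estimator."""
        r = np.random.default_rng(seed)
        counts = {c: int(r.integers(0, 12)) for c in cu.SENSE_CODONS}
        ours = cu.enc(cu.CodonCounts(counts=counts))
        ref = enc_oracle(counts)
        if math.isnan(ref):
            assert math.isnan(ours)
        else:
            assert ours == pytest.approx(ref, abs=1e-9)

    def test_ile_fallback_used_when_missing(self):
        counts = {c: 10 for c in cu.SENSE_CODONS if not c.startswith("AT")}
        comp = cu.enc_components(cu.CodonCounts(counts=counts))
        assert comp.f3_fallback_used
        assert not math.isnan(comp.enc)


class TestGenomeProfile:
    def test_mean_of_two_genes(self):
        seqs = SequenceSet(records={
            "g1": "ATGGCAGCTTAA",  # gc3 = 1/3 (ATG G; GCA A; GCT T)
            "g2": "ATGGCGGCCTAA",  # gc3 = 1
        })
        per_gene, agg = cu.genome_profile(seqs)
        assert agg["mean_gc3"] == pytest.approx((1 / 3 + 1.0) / 2)

    def test_pooled_differs_from_mean_on_heterogeneous_genes(self):
        # one strongly biased gene, one uniform gene: pooling the counts is
        # not the same as averaging per-gene ENC values
        from thermofungi.synthetic_data import gen_cds
        biased = gen_cds(1, 400, 0.5, 1.0, seed=1, id_prefix="b")
        uniform = gen_cds(1, 400, 0.5, 0.0, seed=2, id_prefix="u")
        seqs = SequenceSet(records={**biased.records, **uniform.records})
        _, agg = cu.genome_profile(seqs)
        assert abs(agg["pooled_enc"] - agg["mean_enc"]) > 1.0

    def test_all_genes_skipped_is_error(self):
        with pytest.raises(ValueError, match="all genes skipped"):
            cu.genome_profile(SequenceSet(records={"g1": "ATGG"}))


class TestCompareLifestyles:
    def test_wilcoxon_exact_hand_value(self):
        res = cu.compare_lifestyles(
            {"a": [1, 2, 3], "b": [4, 5, 6]}, test="wilcoxon_rank_sum"
        )
        assert res.p_value == pytest.approx(0.1)

    def test_moods_median_exact_hand_value(self):
        res = cu.compare_lifestyles(
            {"a": [1, 2, 3, 4], "b": [6, 7, 8, 9]}, test="moods_median"
        )
        assert res.p_value == pytest.approx(2 / 70, rel=1e-6)

    def test_identical_groups_p_one(self):
        res = cu.compare_lifestyles(
            {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]}, test="wilcoxon_rank_sum"
        )
        assert res.p_value == pytest.approx(1.0)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            cu.compare_lifestyles({"a": [1.0], "b": [1.0, 2.0]})

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        n1=st.integers(2, 5), n2=st.integers(2, 5), seed=st.integers(0, 10_000)
    )
    def test_wilcoxon_exact_matches_enumeration(self, n1, n2, seed):
        """Exact two-sided p equals full enumeration of rank assignments."""
        r = np.random.default_rng(seed)
        pooled = r.permutation(np.arange(1, n1 + n2 + 1)).astype(float)
        x, y = pooled[:n1], pooled[n1:]
        res = cu.compare_lifestyles({"a": x, "b": y}, test="wilcoxon_rank_sum")
        # enumeration oracle over all C(n1+n2, n1) group assignments of the
        # rank-sum statistic
        values = np.concatenate([x, y])
        ranks = sps.rankdata(values)
        obs = ranks[:n1].sum()
        mu = n1 * (n1 + n2 + 1) / 2
        stats_all = [
            sum(ranks[list(comb)])
            for comb in itertools.combinations(range(n1 + n2), n1)
        ]
        extreme = sum(abs(s - mu) >= abs(obs - mu) - 1e-9 for s in stats_all)
        assert res.p_value == pytest.approx(extreme / len(stats_all), abs=1e-9)


class TestCorrelationQuadrants:
    def test_perfect_anticorrelation(self):
        import pandas as pd
        df = pd.DataFrame({"gc3": [0.1, 0.2, 0.3, 0.4], "enc": [4, 3, 2, 1.0]})
        out = cu.correlation_and_quadrants(df)
        assert out["r"] == pytest.approx(-1.0)
        assert out["r2"] == pytest.approx(1.0)

    def test_boundary_and_quadrant_labels(self):
        import pandas as pd
        df = pd.DataFrame(
            {"gc3": [0.2, 0.6, 0.4], "enc": [55.0, 45.0, 50.0]},
            index=["low", "high", "mid"],
        )
        out = cu.correlation_and_quadrants(df)
        q = out["quadrants"]
        assert q["high"] == "Q1"  # high GC3, low ENC
        assert q["low"] == "Q3"
        assert q["mid"] == "boundary"

    def test_planted_two_cluster_fractions(self):
        import pandas as pd
        df = pd.DataFrame({
            "gc3": [0.7] * 5 + [0.3] * 5,
            "enc": [40.0] * 5 + [55.0] * 5,
            "lifestyle": ["thermophilic"] * 5 + ["mesophilic"] * 5,
        })
        out = cu.correlation_and_quadrants(df)
        frac = out["lifestyle_quadrant_fractions"]
        assert frac.loc["thermophilic", "Q1"] == 1.0
        assert frac.loc["mesophilic", "Q3"] == 1.0

    def test_zero_variance_rejected(self):
        import pandas as pd
        df = pd.DataFrame({"gc3": [0.5, 0.5, 0.5], "enc": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="zero variance"):
            cu.correlation_and_quadrants(df)
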