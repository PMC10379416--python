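import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from looperpop.popgen import (
    GenotypeCounts,
    column_mean_sd,
    del_freq_by_haplotype_group,
    fis,
    haplotype_diversity,
    mean_fis,
    nucleotide_diversity,
    paired_t_test,
    pearson_correlation,
    pooled_fis,
    round_half_up,
)

import _tables as T


# --- independent brute-force oracles ---------------------------------------


def fis_oracle(n_del_hom, n_plus_hom, n_het):
    """F_is from an explicit genotype list, enumerated allele by allele."""
    genotypes = (
        [("del", "del")] * n_del_hom
        + [("plus", "plus")] * n_plus_hom
        + [("del", "plus")] * n_het
    )
    n = len(genotypes)
    h_obs = sum(1 for g in genotypes if g[0] != g[1]) / n
    alleles = [a for g in genotypes for a in g]
    p = alleles.count("del") / len(alleles)
    h_exp = 2 * p * (1 - p)
    if h_exp == 0:
        return None
    return (h_exp - h_obs) / h_exp


def paired_t_oracle(pairs):
    d = [b - a for a, b in pairs]
    k = len(d)
    mean = sum(d) / k
    var = sum((x - mean) ** 2 for x in d) / (k - 1)
    t = mean / math.sqrt(var / k)
    return t, k - 1


def pearson_oracle(x, y):
    k = len(x)
    mx, my = sum(x) / k, sum(y) / k
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def pi_oracle(seqs):
    vals = []
    for a, b in itertools.combinations(seqs, 2):
        cols = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
        if cols:
            vals.append(sum(x != y for x, y in cols) / len(cols))
    return sum(vals) / len(vals)


def h_oracle(seqs):
    n = len(seqs)
    freqs = [seqs.count(s) / n for s in set(seqs)]
    return (n / (n - 1)) * (1 - sum(p * p for p in freqs))


# --- Wright's F_is ----------------------------------------------------------


@pytest.mark.parametrize(
    "counts,expected",
    [(T.MALE_COUNTS[k], T.MALE_FIS[k]) for k in T.MALE_COUNTS]
    + [(T.LARVAL_COUNTS[k], T.LARVAL_FIS[k]) for k in T.LARVAL_COUNTS],
)
def test_fis_reproduces_published_collection_values(counts, expected):
    result = fis(GenotypeCounts(*counts))
    if expected is None:
        assert not result.defined
        assert "no i65del" in result.undefined_reason
    else:
        assert round_half_up(result.fis, 2) == expected


def test_fis_hardy_weinberg_counts_give_zero():
    # H_o == H_e exactly when n_het^2 == 4 * n_del_hom * n_plus_hom
    assert fis(GenotypeCounts(4, 25, 20)).fis == pytest.approx(0.0, abs=1e-15)


def test_fis_no_heterozygotes_gives_one():
    r = fis(GenotypeCounts(4, 24, 0))
    assert r.h_obs == 0.0 and r.h_exp > 0.0
    assert r.fis == pytest.approx(1.0)


def test_fis_zero_specimens_is_an_error():
    with pytest.raises(ValueError):
        fis(GenotypeCounts(0, 0, 0))
    with pytest.raises(ValueError):
        GenotypeCounts(-1, 2, 3)


@given(
    st.integers(0, 80), st.integers(0, 80), st.integers(0, 80)
)
def test_fis_matches_brute_force_enumeration(a, b, c):
    if a + b + c == 0:
        return
    result = fis(GenotypeCounts(a, b, c))
    oracle = fis_oracle(a, b, c)
    if oracle is None:
        assert not result.defined
    else:
        assert result.fis == pytest.approx(oracle, abs=1e-12)
        assert -1.0 <= result.fis <= 1.0


def test_pooled_fis_sums_counts_and_matches_published_totals():
    male = [GenotypeCounts(*v, label=k) for k, v in T.MALE_COUNTS.items()]
    pooled = pooled_fis(male)
    assert (
        sum(c.n_del_hom for c in male),
        sum(c.n_plus_hom for c in male),
        sum(c.n_het for c in male),
    ) == T.MALE_COLUMN_SUM
    assert round_half_up(pooled.fis, 2) == T.MALE_POOLED_FIS
    # the published total row itself rounds to the same pooled value
    assert (
        round_half_up(fis(GenotypeCounts(*T.MALE_TOTAL_PUBLISHED)).fis, 2)
        == T.MALE_POOLED_FIS
    )
    single = GenotypeCounts(3, 5, 2)
    assert pooled_fis([single]).fis == fis(single).fis


def test_mean_fis_skips_undefined_and_matches_published_means():
    male = [GenotypeCounts(*v) for v in T.MALE_COUNTS.values()]
    assert round_half_up(mean_fis(male), 2) == T.MALE_MEAN_FIS
    larval = [GenotypeCounts(*v) for v in T.LARVAL_COUNTS.values()]
    assert round_half_up(mean_fis(larval), 2) == T.LARVAL_MEAN_FIS
    same = [GenotypeCounts(2, 5, 3)] * 4
    assert mean_fis(same) == pytest.approx(fis(same[0]).fis)
    with pytest.raises(ValueError):
        mean_fis([GenotypeCounts(0, 10, 0)])


def test_mixed_sex_sampling_inflates_fis_estimate():
    """Hemizygous females scored as homozygotes depress observed
    heterozygosity, so unknown-sex collections overestimate F_is
    relative to males-only sampling from the same population."""
    from looperpop import SimulationConfig, simulate_collection

    def estimated_fis(sex_mode, seed):
        cfg = SimulationConfig(
            n_specimens=8000, seed=seed, clan_proportion_B=0.5,
            p_del_given_A=0.1, p_del_given_B=0.5,
            hybridization_rate=0.2, sex_mode=sex_mode,
        )
        tallies = {"hom_del": 0, "hom_plus": 0, "het": 0}
        for s in simulate_collection(cfg):
            alleles = set(s.z_alleles)
            if alleles == {"del", "plus"}:
                tallies["het"] += 1
            elif alleles == {"del"}:
                tallies["hom_del"] += 1
            else:
                tallies["hom_plus"] += 1
        return fis(
            GenotypeCounts(tallies["hom_del"], tallies["hom_plus"], tallies["het"])
        ).fis

    assert estimated_fis("unknown", 101) > estimated_fis("males_only", 101)


# --- grouped allele frequencies --------------------------------------------


def make_specimens(rows):
    return pd.DataFrame(
        rows, columns=["state", "coi_class", "tpi_genotype", "sex"]
    )


def test_all_del_homozygotes_give_100_percent_in_both_columns():
    rows = [("XX", hap, "del_only", "male") for hap in ["C1035"] * 12 + ["T1035"] * 12]
    out = del_freq_by_haplotype_group(make_specimens(rows))
    assert len(out) == 1
    assert out[0].freq_del_in_C1035 == 100.0
    assert out[0].freq_del_in_T1035 == 100.0


def test_undersampled_units_merge_into_pool():
    rows = []
    # 'BIG' passes the threshold in both classes; 'TINY' has only 9
    # T1035 specimens and must be pooled regardless of its C1035 count
    rows += [("BIG", "C1035", "plus_only", "male")] * 12
    rows += [("BIG", "T1035", "del_only", "male")] * 12
    rows += [("TINY", "C1035", "plus_only", "male")] * 30
    rows += [("TINY", "T1035", "del_only", "male")] * 9
    out = del_freq_by_haplotype_group(make_specimens(rows))
    units = [r.unit for r in out]
    assert units == ["BIG", "Pool"]
    pool = out[-1]
    assert pool.n == 39


def test_female_hemizygotes_counted_as_single_alleles():
    rows = (
        [("ST", "C1035", "del_only", "female")] * 10  # 10 del of 10 alleles
        + [("ST", "C1035", "plus_only", "male")] * 5  # 0 del of 10
        + [("ST", "T1035", "heterozygous", "male")] * 10  # 10 del of 20
    )
    out = del_freq_by_haplotype_group(make_specimens(rows))
    assert out[0].freq_del_in_C1035 == pytest.approx(50.0)
    assert out[0].freq_del_in_T1035 == pytest.approx(50.0)


def test_no_callable_specimens_is_an_error():
    with pytest.raises(ValueError):
        del_freq_by_haplotype_group(
            make_specimens([("ST", "uncallable", "uncallable", "male")])
        )


# --- classical statistics ---------------------------------------------------


def test_paired_t_reproduces_published_state_comparison():
    pairs = [(c, t) for _, c, t in T.STATE_DEL_FREQ_PAIRS]
    res = paired_t_test(pairs)
    assert res.t == pytest.approx(T.STATE_T, abs=5e-4)
    assert res.df == T.STATE_DF
    mc, sc = column_mean_sd([p[0] for p in pairs])
    mt, st_ = column_mean_sd([p[1] for p in pairs])
    assert (round(mc), round(sc)) == T.STATE_MEAN_C
    assert (round(mt), round(st_)) == T.STATE_MEAN_T


@given(st.integers(0, 500))
def test_paired_t_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    k = int(rng.integers(3, 12))
    pairs = [(float(a), float(b)) for a, b in rng.normal(10, 4, size=(k, 2))]
    t_o, df_o = paired_t_oracle(pairs)
    res = paired_t_test(pairs)
    assert res.t == pytest.approx(t_o, abs=1e-12)
    assert res.df == df_o


def test_paired_t_zero_variance_is_an_error():
    with pytest.raises(ValueError):
        paired_t_test([(1.0, 3.0), (2.0, 4.0), (5.0, 7.0)])
    with pytest.raises(ValueError):
        paired_t_test([(1.0, 1.0), (2.0, 2.0)])


@given(st.integers(0, 500))
def test_pearson_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    k = int(rng.integers(3, 15))
    x = rng.normal(size=k)
    y = rng.normal(size=k)
    r, _ = pearson_correlation(x, y)
    assert r == pytest.approx(pearson_oracle(list(x), list(y)), abs=1e-12)


def test_pearson_exact_cases_and_p_transform():
    r, _ = pearson_correlation([1, 2, 3, 4], [3, 5, 7, 9])
    assert r == pytest.approx(1.0)
    r, _ = pearson_correlation([1, 2, 3, 4], [-1, -2, -3, -4])
    assert r == pytest.approx(-1.0)
    # r = 0.630 over 21 points corresponds to p near 0.002 under the
    # exact t transform t = r sqrt(k-2)/sqrt(1-r^2)
    from scipy import stats as sps

    k, r = 21, 0.630
    t = r * math.sqrt(k - 2) / math.sqrt(1 - r * r)
    p = 2 * sps.t.sf(t, df=k - 2)
    assert p == pytest.approx(0.002, abs=8e-4)
    with pytest.raises(ValueError):
        pearson_correlation([1, 1, 1], [1, 2, 3])


# --- diversity --------------------------------------------------------------


def test_haplotype_diversity_examples():
    assert haplotype_diversity(["AAA"] * 5)[0] == 0.0
    assert haplotype_diversity(["AAA", "AAT"])[0] == pytest.approx(1.0)
    seqs = ["AAA"] * 9 + ["AAT"]
    assert haplotype_diversity(seqs)[0] == pytest.approx((10 / 9) * (1 - 0.82))
    with pytest.raises(ValueError):
        haplotype_diversity(["AAA"])


def test_nucleotide_diversity_examples():
    assert nucleotide_diversity(["ACGT", "ACGT"])[0] == 0.0
    assert nucleotide_diversity(["A" * 10, "A" * 8 + "TT"])[0] == pytest.approx(0.2)
    # pairwise distances 1, 2, 3 over length 100 -> mean 0.02
    s1 = "A" * 100
    s2 = "T" + "A" * 99
    s3 = "TC" + "A" * 97 + "G"
    assert nucleotide_diversity([s1, s2, s3])[0] == pytest.approx(0.02)
    # gapped columns excluded pair-wise
    assert nucleotide_diversity(["AC-T", "ACGT"])[0] == 0.0


@given(st.integers(0, 300))
def test_diversity_matches_oracles_and_is_order_invariant(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 10))
    pool = ["".join(rng.choice(list("ACGT-"), size=12)) for _ in range(4)]
    seqs = [pool[i] for i in rng.integers(0, len(pool), size=n)]
    if all("".join(s).replace("-", "") == "" for s in seqs):
        return
    try:
        pi, _ = nucleotide_diversity(seqs)
    except ValueError:
        return
    assert pi == pytest.approx(pi_oracle(seqs), abs=1e-12)
    h, _ = haplotype_diversity(seqs)
    assert h == pytest.approx(h_oracle(seqs), abs=1e-12)
    perm = [seqs[i] for i in rng.permutation(n)]
    assert nucleotide_diversity(perm)[0] == pytest.approx(pi, abs=1e-12)
    assert haplotype_diversity(perm)[0] == pytest.approx(h, abs=1e-12)


def test_clan_proxy_summary_recovers_configured_marker_frequencies():
    """With the del allele absent in clan A and fixed in clan B and no
    cross-mating, the i65del proxy recovers each clan's configured
    T1035 frequency (17% / 41%) within 3 binomial standard errors."""
    from looperpop import SimulationConfig, default_reference, simulate_collection
    from looperpop.popgen import clan_marker_summary

    ref = default_reference()
    cfg = SimulationConfig(
        n_specimens=4000, seed=77, clan_proportion_B=0.4,
        p_T1035_given_A=0.17, p_T1035_given_B=0.41,
        p_del_given_A=0.0, p_del_given_B=1.0,
        hybridization_rate=0.0, sex_mode="males_only",
    )
    specimens = simulate_collection(cfg, ref)
    df = pd.DataFrame(
        {
            "coi_class": [s.mito_haplotype for s in specimens],
            "tpi_genotype": [
                "heterozygous" if set(s.z_alleles) == {"del", "plus"}
                else "del_only" if set(s.z_alleles) == {"del"}
                else "plus_only"
                for s in specimens
            ],
            "tpi_read": [s.tpi_read for s in specimens],
        }
    )
    summary = clan_marker_summary(
        df, plus_consensus=ref.tpi_plus_consensus, del_consensus=ref.tpi_del_consensus
    )
    by_clan = summary.set_index("clan")
    assert by_clan.loc["A", "pct_i65del"] == 0.0
    assert by_clan.loc["B", "pct_i65del"] == 100.0
    for clan, p_true in (("A", 0.17), ("B", 0.41)):
        n = by_clan.loc[clan, "n_specimens"]
        se = 100 * math.sqrt(p_true * (1 - p_true) / n)
        assert abs(by_clan.loc[clan, "pct_T1035"] - 100 * p_true) < 3 * se


def test_clan_summary_with_no_del_alleles_reports_empty_clan_b():
    from looperpop.popgen import clan_marker_summary

    df = pd.DataFrame(
        {
            "coi_class": ["T1035", "C1035", "C1035"],
            "tpi_genotype": ["plus_only"] * 3,
            "tpi_read": ["ACGT"] * 3,
        }
    )
    summary = clan_marker_summary(df).set_index("clan")
    assert summary.loc["B", "n_specimens"] == 0
    assert math.isnan(summary.loc["B", "pct_T1035"])
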