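"""Population-genetic statistics for the two-marker analysis.

Implements Wright's local inbreeding coefficient
F_is = (H_e − H_o) / H_e from three-class Tpi genotype counts, the
grouped i65del allele-frequency comparison between mitochondrial
haplotype classes (with pooling of under-sampled units), paired
t-tests, Pearson correlation, and haplotype / nucleotide diversity with
Nei's large-sample standard deviations.

Hemizygous specimens of unknown sex are scored with the same diploid
formula as males (a hemizygote counts as a homozygote). This biases
F_is upward — females cannot be heterozygous — and the bias is treated
as an explicit, documented property of the estimator, not an error.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

POOL_LABEL = "Pool"
CALLABLE_GENOTYPES = ("del_only", "plus_only", "heterozygous")


@dataclass(frozen=True)
class GenotypeCounts:
    """Per-collection counts of the three Tpi genotype classes.

    ``n_del_hom`` counts i65del/i65del males plus i65del hemizygotes
    when sex is unknown; ``n_plus_hom`` the same for i65+.
    """

    n_del_hom: int
    n_plus_hom: int
    n_het: int
    label: str = ""

    def __post_init__(self) -> None:
        if min(self.n_del_hom, self.n_plus_hom, self.n_het) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def n(self) -> int:
        return self.n_del_hom + self.n_plus_hom + self.n_het


@dataclass(frozen=True)
class FisResult:
    """Observed/expected heterozygosity and F_is, with an explicit
    undefined state for monomorphic samples (reported as "nd")."""

    p_del: float
    h_obs: float
    h_exp: float
    fis: Optional[float]
    undefined_reason: str = ""
    label: str = ""

    @property
    def defined(self) -> bool:
        return self.fis is not None


@dataclass(frozen=True)
class GroupFrequencyRow:
    """i65del percent frequency within each mito-haplotype class for one unit."""

    unit: str
    n: int
    freq_del_in_C1035: float
    freq_del_in_T1035: float


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p_two_sided: float
    mean_diff: float


@dataclass(frozen=True)
class DiversityMetrics:
    haplotype_diversity: float
    haplotype_diversity_sd: float
    nucleotide_diversity: float
    nucleotide_diversity_sd: float
    n_sequences: int
    n_haplotypes: int


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding for report display (0.405 -> 0.41)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def fis(counts: GenotypeCounts) -> FisResult:
    """Wright's F_is = (H_e − H_o)/H_e from three-class genotype counts.

    H_o = n_het / n; p = (2·n_del_hom + n_het) / 2n; H_e = 2p(1−p).
    Monomorphic samples (H_e = 0) yield the undefined state.
    """
    n = counts.n
    if n == 0:
        raise ValueError("cannot compute F_is from zero specimens")
    h_obs = counts.n_het / n
    p = (2 * counts.n_del_hom + counts.n_het) / (2 * n)
    h_exp = 2.0 * p * (1.0 - p)
    if h_exp == 0.0:
        which = "i65del" if p == 0.0 else "i65+"
        return FisResult(
            p_del=p,
            h_obs=h_obs,
            h_exp=h_exp,
            fis=None,
            undefined_reason=f"no {which} alleles detected",
            label=counts.label,
        )
    return FisResult(
        p_del=p,
        h_obs=h_obs,
        h_exp=h_exp,
        fis=(h_exp - h_obs) / h_exp,
        label=counts.label,
    )


def pooled_fis(counts_list: Sequence[GenotypeCounts]) -> FisResult:
    """F_is of the element-wise sum of several collections' counts."""
    if not counts_list:
        raise ValueError("empty counts list")
    total = GenotypeCounts(
        n_del_hom=sum(c.n_del_hom for c in counts_list),
        n_plus_hom=sum(c.n_plus_hom for c in counts_list),
        n_het=sum(c.n_het for c in counts_list),
        label="Total",
    )
    return fis(total)


def mean_fis(counts_list: Sequence[GenotypeCounts]) -> float:
    """Arithmetic mean of the full-precision per-collection F_is values,
    skipping undefined (monomorphic) collections."""
    values = [r.fis for r in map(fis, counts_list) if r.fis is not None]
    if not values:
        raise ValueError("F_is undefined for every collection")
    return float(np.mean(values))


# --- grouped allele frequencies (mito-haplotype classes) -------------------


def _allele_counts(group: pd.DataFrame) -> Tuple[int, int]:
    """(del alleles, total alleles) for a set of called specimens.

    Males and unknown-sex specimens contribute two alleles (a
    heterozygote contributes one del); known females are hemizygous and
    contribute one.
    """
    del_count = 0
    total = 0
    for _, row in group.iterrows():
        geno = row["tpi_genotype"]
        if geno not in ("del_only", "plus_only", "heterozygous"):
            continue
        n_alleles = 1 if row.get("sex", "unknown") == "female" else 2
        if geno == "del_only":
            del_count += n_alleles
        elif geno == "heterozygous":
            del_count += 1
        total += n_alleles
    return del_count, total


def del_freq_by_haplotype_group(
    specimens: pd.DataFrame,
    group_by: str = "state",
    min_per_class: int = 10,
) -> List[GroupFrequencyRow]:
    """i65del percent frequency within C1035 and T1035 specimens, per unit.

    ``specimens`` needs columns ``coi_class`` (T1035/C1035),
    ``tpi_genotype`` (del_only/plus_only/heterozygous), ``sex`` and the
    grouping column. Units with fewer than ``min_per_class`` specimens
    of *either* haplotype class are merged into a single "Pool" unit.
    """
    df = specimens[
        specimens["coi_class"].isin(["T1035", "C1035"])
        & specimens["tpi_genotype"].isin(["del_only", "plus_only", "heterozygous"])
    ].copy()
    if df.empty:
        raise ValueError("no specimens with callable COI and Tpi results")
    units = []
    pooled_units = []
    for unit, grp in df.groupby(group_by, sort=True):
        n_c = int((grp["coi_class"] == "C1035").sum())
        n_t = int((grp["coi_class"] == "T1035").sum())
        if n_c < min_per_class or n_t < min_per_class:
            pooled_units.append(unit)
        else:
            units.append(unit)
    df["_unit"] = [
        POOL_LABEL if u in pooled_units else u for u in df[group_by]
    ]
    rows: List[GroupFrequencyRow] = []
    for unit, grp in df.groupby("_unit", sort=True):
        freqs = {}
        for hap in ("C1035", "T1035"):
            d, tot = _allele_counts(grp[grp["coi_class"] == hap])
            freqs[hap] = 100.0 * d / tot if tot else float("nan")
        rows.append(
            GroupFrequencyRow(
                unit=str(unit),
                n=len(grp),
                freq_del_in_C1035=freqs["C1035"],
                freq_del_in_T1035=freqs["T1035"],
            )
        )
    # keep Pool last for table layout
    rows.sort(key=lambda r: (r.unit == POOL_LABEL, r.unit))
    return rows


# --- classical statistics ---------------------------------------------------


def paired_t_test(pairs: Sequence[Tuple[float, float]]) -> PairedTResult:
    """Two-sided paired t-test on (first, second) value pairs.

    t = mean(d) / (sd(d)/√k) with d = second − first and the
    (k−1)-denominator sample sd; df = k − 1.
    """
    if len(pairs) < 2:
        raise ValueError("need at least two pairs")
    first = np.asarray([p[0] for p in pairs], dtype=float)
    second = np.asarray([p[1] for p in pairs], dtype=float)
    d = second - first
    if np.std(d, ddof=1) == 0.0:
        raise ValueError("zero variance of within-pair differences")
    res = stats.ttest_rel(second, first)
    return PairedTResult(
        t=float(res.statistic),
        df=len(pairs) - 1,
        p_two_sided=float(res.pvalue),
        mean_diff=float(np.mean(d)),
    )


def column_mean_sd(values: Sequence[float]) -> Tuple[float, float]:
    """Arithmetic mean and (k−1)-denominator sd of one table column."""
    if len(values) < 2:
        raise ValueError("need at least two values")
    arr = np.asarray(values, dtype=float)
    return float(np.mean(arr)), float(np.std(arr, ddof=1))


def pearson_correlation(
    x: Sequence[float], y: Sequence[float]
) -> Tuple[float, float]:
    """Product-moment r with the exact two-sided p from
    t = r·√(k−2)/√(1−r²) on k−2 degrees of freedom."""
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least three points")
    ax, ay = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if np.std(ax) == 0.0 or np.std(ay) == 0.0:
        raise ValueError("zero variance in one of the vectors")
    r, p = stats.pearsonr(ax, ay)
    return float(r), float(p)


# --- sequence diversity -----------------------------------------------------


def haplotype_diversity(sequences: Sequence[str]) -> Tuple[float, float]:
    """Nei's haplotype (gene) diversity h with its large-sample sd.

    h = (n/(n−1))·(1 − Σ p_i²) over distinct-sequence frequencies;
    the variance is Nei's estimator
    V(h) = 2/(n(n−1)) · {2(n−2)[Σp³ − (Σp²)²] + Σp² − (Σp²)²}.
    """
    n = len(sequences)
    if n < 2:
        raise ValueError("need at least two sequences")
    counts = pd.Series(list(sequences)).value_counts()
    p = counts.to_numpy(dtype=float) / n
    sum2 = float(np.sum(p**2))
    sum3 = float(np.sum(p**3))
    h = (n / (n - 1)) * (1.0 - sum2)
    var = (2.0 / (n * (n - 1))) * (
        2.0 * (n - 2) * (sum3 - sum2**2) + sum2 - sum2**2
    )
    return h, float(np.sqrt(max(var, 0.0)))


def _pairwise_pi(a: str, b: str) -> Optional[float]:
    """Proportion of differing sites between two aligned sequences,
    skipping columns gapped in either member; None when no column is
    comparable."""
    x = np.frombuffer(a.encode(), dtype="S1")
    y = np.frombuffer(b.encode(), dtype="S1")
    ok = (x != b"-") & (y != b"-")
    compared = int(ok.sum())
    if compared == 0:
        return None
    return int((x[ok] != y[ok]).sum()) / compared


def nucleotide_diversity(sequences: Sequence[str]) -> Tuple[float, float]:
    """Nucleotide diversity π (mean pairwise difference per site) with
    the no-recombination sampling sd of Nei/Tajima:
    V(π) = (n+1)/(3(n−1)L)·π + 2(n²+n+3)/(9n(n−1))·π².

    Identical sequences are collapsed and distinct-haplotype pairs
    weighted by their multiplicities, so large collections dominated by
    a few haplotypes cost far fewer than n² comparisons.
    """
    n = len(sequences)
    if n < 2:
        raise ValueError("need at least two sequences")
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError("sequences must be aligned to equal length")
    counts = pd.Series(list(sequences)).value_counts()
    haps = list(counts.index)
    mult = counts.to_numpy()
    total_w = 0.0
    total = 0.0
    for i, j in itertools.combinations(range(len(haps)), 2):
        v = _pairwise_pi(haps[i], haps[j])
        if v is None:
            continue
        w = mult[i] * mult[j]
        total += w * v
        total_w += w
    # within-haplotype pairs differ at zero sites but count in the mean
    for i, c in enumerate(mult):
        if c >= 2 and haps[i].replace("-", ""):
            total_w += c * (c - 1) / 2
    if total_w == 0:
        raise ValueError("no comparable (ungapped) site pairs")
    pi = total / total_w
    L = lengths.pop()
    var = ((n + 1) / (3.0 * (n - 1) * L)) * pi + (
        2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    ) * pi**2
    return pi, float(np.sqrt(max(var, 0.0)))


def diversity_metrics(sequences: Sequence[str]) -> DiversityMetrics:
    h, h_sd = haplotype_diversity(sequences)
    pi, pi_sd = nucleotide_diversity(sequences)
    return DiversityMetrics(
        haplotype_diversity=h,
        haplotype_diversity_sd=h_sd,
        nucleotide_diversity=pi,
        nucleotide_diversity_sd=pi_sd,
        n_sequences=len(sequences),
        n_haplotypes=len(set(sequences)),
    )


# --- clan summary (i65del as the clan proxy) -------------------------------


def clan_marker_summary(
    specimens: pd.DataFrame,
    plus_consensus: Optional[str] = None,
    del_consensus: Optional[str] = None,
) -> pd.DataFrame:
    """Clan-level marker table using the i65del allele as the clan proxy.

    i65+ alleles define proxy-ClanA, i65del alleles proxy-ClanB;
    heterozygotes carry one allele of each class and contribute to both
    clans (per-allele accounting). Reported per clan: specimen count,
    the definitional i65del fraction (0%/100%), the T1035 fraction
    among specimens carrying that allele class, and haplotype /
    nucleotide diversity of the clan's Tpi sequences. Hemizygous and
    homozygous specimens contribute their own read; a heterozygote's
    two alleles cannot be phased apart from its superimposed read, so
    it contributes the reference consensus of each allele when those
    are supplied.
    """
    df = specimens[
        specimens["tpi_genotype"].isin(["del_only", "plus_only", "heterozygous"])
    ]
    if df.empty:
        raise ValueError("no specimens with callable Tpi results")
    has_coi = df["coi_class"].isin(["T1035", "C1035"])
    rows = []
    for clan, own_geno, het_seq in (
        ("A", "plus_only", plus_consensus),
        ("B", "del_only", del_consensus),
    ):
        carriers = df[df["tpi_genotype"].isin([own_geno, "heterozygous"])]
        n_specimens = len(carriers)
        coi_known = carriers[has_coi.reindex(carriers.index, fill_value=False)]
        t_frac = (
            100.0 * float((coi_known["coi_class"] == "T1035").mean())
            if len(coi_known)
            else float("nan")
        )
        seqs: List[str] = []
        have_reads = "tpi_read" in carriers.columns
        for _, row in carriers.iterrows():
            if row["tpi_genotype"] == own_geno:
                if have_reads:
                    seqs.append(row["tpi_read"])
                elif het_seq is not None:
                    seqs.append(het_seq)
            elif row["tpi_genotype"] == "heterozygous" and het_seq is not None:
                seqs.append(het_seq)
        if len(seqs) >= 2:
            mets = diversity_metrics(seqs)
            h, h_sd = mets.haplotype_diversity, mets.haplotype_diversity_sd
            pi, pi_sd = mets.nucleotide_diversity, mets.nucleotide_diversity_sd
        else:
            h = h_sd = pi = pi_sd = float("nan")
        rows.append(
            {
                "clan": clan,
                "n_specimens": n_specimens,
                "pct_i65del": 0.0 if clan == "A" else 100.0,
                "pct_T1035": t_frac,
                "haplotype_diversity": h,
                "haplotype_diversity_sd": h_sd,
                "nucleotide_diversity": pi,
                "nucleotide_diversity_sd": pi_sd,
            }
        )
    return pd.DataFrame(rows)


def genotype_counts_from_calls(
    specimens: pd.DataFrame, label: str = ""
) -> GenotypeCounts:
    """Tabulate called specimens into the three-genotype count vector.

    Known females are excluded: a hemizygote of known sex carries no
    information about heterozygote deficit. Unknown-sex specimens are
    kept and scored as diploid, the convention used throughout the
    reporting layer.
    """
    df = specimens[specimens["tpi_genotype"].isin(["del_only", "plus_only", "heterozygous"])]
    df = df[df.get("sex", pd.Series("unknown", index=df.index)) != "female"]
    return GenotypeCounts(
        n_del_hom=int((df["tpi_genotype"] == "del_only").sum()),
        n_plus_hom=int((df["tpi_genotype"] == "plus_only").sum()),
        n_het=int((df["tpi_genotype"] == "heterozygous").sum()),
        label=label,
    )
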