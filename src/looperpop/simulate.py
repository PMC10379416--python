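"""Two-clan forward simulator with Lepidopteran (ZZ/ZW) sex genetics.

Emulates field collections of soybean looper drawn from a mixture of
two subpopulations ("clans") that differ in marker frequencies:

* the mitochondrial haplotype (T1035 vs C1035) is maternally inherited
  and drawn from the mother clan's frequency;
* the Z-linked Tpi locus is biallelic (i65del vs i65+). Males (ZZ)
  receive one Z from each parent; females (ZW) receive their single Z
  from the father.

Cross-hybridization between clans is a single per-specimen probability
``m``: the father's clan equals the mother's with probability 1 − m.
At m = 0 the pooled genotypes show the Wahlund heterozygote deficit
F_is = (p_A − p_B)² / (4 p̄ q̄) for equal clan proportions, and the
mito–nuclear association emerges with no explicit coupling; at full
random mixing (m = 0.5 with equal proportions) F_is = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .calling import expected_het_signature
from .reference import MarkerReference, default_reference

SEX_MODES = ("males_only", "random_half", "unknown")
CLANS = ("A", "B")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated collection.

    Marker-frequency defaults are the clan values estimated in the
    field study this package models: the i65del allele is absent from
    ClanA and fixed in ClanB, while the T1035 mitochondrial haplotype
    is at 17% in ClanA and 41% in ClanB.
    """

    n_specimens: int
    seed: int
    clan_proportion_B: float = 0.12
    p_T1035_given_A: float = 0.17
    p_T1035_given_B: float = 0.41
    p_del_given_A: float = 0.0
    p_del_given_B: float = 1.0
    hybridization_rate: float = 0.1
    sex_mode: str = "males_only"
    collection_label: str = "SIM"
    state: str = "NA"
    year: int = 2020
    collection_type: str = "simulated"
    noise_rate: float = 0.0

    def validate(self) -> None:
        for name in (
            "clan_proportion_B",
            "p_T1035_given_A",
            "p_T1035_given_B",
            "p_del_given_A",
            "p_del_given_B",
            "hybridization_rate",
            "noise_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= float(v) <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if int(self.n_specimens) < 1:
            raise ValueError(f"n_specimens={self.n_specimens} must be >= 1")
        if self.sex_mode not in SEX_MODES:
            raise ValueError(f"sex_mode must be one of {SEX_MODES}")

    def to_dict(self) -> dict:
        return {
            "n_specimens": self.n_specimens,
            "seed": self.seed,
            "clan_proportion_B": self.clan_proportion_B,
            "p_T1035_given_A": self.p_T1035_given_A,
            "p_T1035_given_B": self.p_T1035_given_B,
            "p_del_given_A": self.p_del_given_A,
            "p_del_given_B": self.p_del_given_B,
            "hybridization_rate": self.hybridization_rate,
            "sex_mode": self.sex_mode,
            "collection_label": self.collection_label,
            "state": self.state,
            "year": self.year,
            "collection_type": self.collection_type,
            "noise_rate": self.noise_rate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class TrueSpecimen:
    """One simulated individual with its latent state and rendered reads.

    ``z_alleles`` holds one allele ("del"/"plus") for females and an
    unordered pair for males. The tpi read contains IUPAC ambiguity
    characters only when the specimen is a male carrying two distinct
    alleles.
    """

    specimen_id: str
    true_mother_clan: str
    true_father_clan: str
    sex: str  # male | female | unknown
    mito_haplotype: str  # T1035 | C1035
    z_alleles: Tuple[str, ...]
    coi_read: str
    tpi_read: str
    collection: str = "SIM"
    state: str = "NA"
    year: int = 2020
    collection_type: str = "simulated"


def render_coi_read(
    haplotype: str,
    site1272_base: str,
    ref: MarkerReference,
    noise_rate: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> str:
    """Render an sCOIB read: the template with the two SNP sites set.

    Optional uniform substitution noise never touches the SNP sites or
    their anchor flanks, so noise degrades overall identity without
    corrupting the positions the caller keys on.
    """
    if haplotype not in ("T1035", "C1035"):
        raise ValueError(f"unknown haplotype {haplotype!r}")
    if site1272_base not in "CT":
        raise ValueError(f"site-1272 base must be C or T, got {site1272_base!r}")
    if not 0.0 <= noise_rate <= 1.0:
        raise ValueError(f"noise_rate={noise_rate} outside [0, 1]")
    seq = list(ref.coi_template)
    seq[ref.site_1035_offset] = "T" if haplotype == "T1035" else "C"
    seq[ref.site_1272_offset] = site1272_base
    if noise_rate > 0.0:
        if rng is None:
            rng = np.random.default_rng()
        k = ref.anchor_k
        protected = set()
        for off in (ref.site_1035_offset, ref.site_1272_offset):
            protected.update(range(off - k, off + k + 1))
        hits = np.nonzero(rng.random(len(seq)) < noise_rate)[0]
        for i in hits:
            if int(i) in protected:
                continue
            others = [b for b in "ACGT" if b != seq[i]]
            seq[i] = others[int(rng.integers(3))]
    return "".join(seq)


def render_tpi_read(z_alleles: Sequence[str], ref: MarkerReference) -> str:
    """Render an sTpiI140 read from one or two Tpi alleles.

    Hemizygotes and homozygotes read as the corresponding allele
    consensus; del/+ heterozygotes read as the frameshifted IUPAC
    superimposition beginning at the deletion breakpoint (identical to
    ``expected_het_signature``).
    """
    alleles = tuple(z_alleles)
    if not 1 <= len(alleles) <= 2 or any(a not in ("del", "plus") for a in alleles):
        raise ValueError(f"z_alleles must be 1 or 2 of {{'del', 'plus'}}, got {alleles!r}")
    distinct = set(alleles)
    if distinct == {"plus"}:
        return ref.tpi_plus_consensus
    if distinct == {"del"}:
        return ref.tpi_del_consensus
    return expected_het_signature(ref)


def _draw_clan(rng: np.random.Generator, p_B: float) -> str:
    return "B" if rng.random() < p_B else "A"


def simulate_collection(
    config: SimulationConfig, ref: Optional[MarkerReference] = None
) -> List[TrueSpecimen]:
    """Simulate one collection of specimens under the two-clan model.

    Per specimen: the mother's clan is Bernoulli(clan_proportion_B); the
    father matches her clan with probability 1 − m and crosses with
    probability m; the mitochondrial haplotype follows the mother clan's
    T1035 frequency; Z alleles are drawn per-parent from the clan del
    frequencies (males one from each parent, females one from the
    father). Identical (config, seed) gives identical output.
    """
    config.validate()
    if ref is None:
        ref = default_reference()
    rng = np.random.default_rng(config.seed)
    m = config.hybridization_rate
    p_T = {"A": config.p_T1035_given_A, "B": config.p_T1035_given_B}
    p_del = {"A": config.p_del_given_A, "B": config.p_del_given_B}

    out: List[TrueSpecimen] = []
    width = max(4, len(str(config.n_specimens)))
    for i in range(config.n_specimens):
        mother = _draw_clan(rng, config.clan_proportion_B)
        if rng.random() < m:
            father = "A" if mother == "B" else "B"
        else:
            father = mother
        if config.sex_mode == "males_only":
            sex = "male"
        elif config.sex_mode == "random_half":
            sex = "male" if rng.random() < 0.5 else "female"
        else:
            sex = "unknown"
        hap = "T1035" if rng.random() < p_T[mother] else "C1035"
        # the predominant four-way classes pair T1035 with C1272 and
        # C1035 with T1272
        b1272 = "C" if hap == "T1035" else "T"
        # an unknown-sex specimen is still biologically male or female;
        # draw the latent sex so hemizygotes occur at realistic rates
        latent_female = sex == "female" or (
            sex == "unknown" and rng.random() < 0.5
        )
        if latent_female:
            alleles: Tuple[str, ...] = (
                "del" if rng.random() < p_del[father] else "plus",
            )
        else:
            a_m = "del" if rng.random() < p_del[mother] else "plus"
            a_f = "del" if rng.random() < p_del[father] else "plus"
            alleles = tuple(sorted((a_m, a_f)))
        coi = render_coi_read(hap, b1272, ref, config.noise_rate, rng)
        tpi = render_tpi_read(alleles, ref)
        out.append(
            TrueSpecimen(
                specimen_id=f"{config.collection_label}_{i:0{width}d}",
                true_mother_clan=mother,
                true_father_clan=father,
                sex=sex,
                mito_haplotype=hap,
                z_alleles=alleles,
                coi_read=coi,
                tpi_read=tpi,
                collection=config.collection_label,
                state=config.state,
                year=config.year,
                collection_type=config.collection_type,
            )
        )
    return out


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(config, seed=seed)
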