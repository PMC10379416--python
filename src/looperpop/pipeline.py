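"""End-to-end orchestration: simulate (or load) → call → statistics.

One reproducible run produces a per-specimen call table, a grouped
allele-frequency report with its paired t-test, an F_is report
(per collection, pooled, mean), a clan-level marker summary, and a
machine-readable manifest holding every statistic at full precision
alongside its rounded display value. Identical config + seed gives a
byte-identical manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calling import call_coi_haplotype, call_tpi_genotype
from .io import read_fasta, read_metadata, write_calls, write_dataset
from .popgen import (
    FisResult,
    GenotypeCounts,
    POOL_LABEL,
    clan_marker_summary,
    del_freq_by_haplotype_group,
    column_mean_sd,
    fis,
    genotype_counts_from_calls,
    mean_fis,
    paired_t_test,
    pearson_correlation,
    pooled_fis,
    round_half_up,
)
from .reference import MarkerReference, default_reference
from .simulate import SimulationConfig, simulate_collection

log = logging.getLogger("looperpop")


class MissingInputError(FileNotFoundError):
    """An input path named in the config does not exist."""


class ReferenceError(ValueError):
    """The marker reference could not be read or is invalid."""


class EmptyCallSetError(ValueError):
    """No specimen produced a callable genotype."""


@dataclass(frozen=True)
class RunConfig:
    """One pipeline run: either a simulation block or input paths.

    Exactly one of ``simulations`` / ``inputs`` must be present.
    ``inputs`` is a mapping with keys coi_fasta, tpi_fasta, metadata.
    """

    out_dir: str
    seed: int = 0
    simulations: Optional[List[SimulationConfig]] = None
    inputs: Optional[Dict[str, str]] = None
    reference: Optional[MarkerReference] = None
    min_per_class: int = 10
    min_match: float = 0.95

    def validate(self) -> None:
        if (self.simulations is None) == (self.inputs is None):
            raise ValueError("exactly one of simulations/inputs must be given")

    def to_dict(self) -> dict:
        d: dict = {
            "out_dir": self.out_dir,
            "seed": self.seed,
            "min_per_class": self.min_per_class,
            "min_match": self.min_match,
        }
        if self.simulations is not None:
            d["simulations"] = [s.to_dict() for s in self.simulations]
        if self.inputs is not None:
            d["inputs"] = dict(self.inputs)
        if self.reference is not None:
            d["reference"] = self.reference.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        ref = None
        if "reference" in d and d["reference"] is not None:
            try:
                ref = MarkerReference.from_dict(d["reference"])
            except (KeyError, ValueError, TypeError) as exc:
                raise ReferenceError(str(exc)) from exc
        sims = None
        if d.get("simulations") is not None:
            sims = [SimulationConfig.from_dict(s) for s in d["simulations"]]
        return cls(
            out_dir=d["out_dir"],
            seed=int(d.get("seed", 0)),
            simulations=sims,
            inputs=d.get("inputs"),
            reference=ref,
            min_per_class=int(d.get("min_per_class", 10)),
            min_match=float(d.get("min_match", 0.95)),
        )

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        if not os.path.exists(path):
            raise MissingInputError(path)
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def call_dataset(
    coi_reads: Sequence,
    tpi_reads: Sequence,
    ref: MarkerReference,
    min_match: float = 0.95,
) -> pd.DataFrame:
    """Call both markers for id-matched read lists.

    Returns one row per specimen with coi_class, combined_class,
    tpi_genotype and match fractions; specimens present in only one
    FASTA get an uncallable result for the missing marker.
    """
    coi_map = dict(coi_reads)
    tpi_map = dict(tpi_reads)
    ids = list(dict.fromkeys(list(coi_map) + list(tpi_map)))
    rows = []
    for sid in ids:
        coi_read = coi_map.get(sid)
        tpi_read = tpi_map.get(sid)
        if coi_read:
            c = call_coi_haplotype(coi_read, ref)
            coi_class, combined = c.haplotype_class, c.combined_class
        else:
            coi_class, combined = "uncallable", "other"
        if tpi_read:
            t = call_tpi_genotype(tpi_read, ref, min_match=min_match)
            tpi_genotype, match = t.genotype, t.signature_match_fraction
        else:
            tpi_genotype, match = "uncallable", 0.0
        rows.append(
            {
                "specimen_id": sid,
                "coi_class": coi_class,
                "combined_class": combined,
                "tpi_genotype": tpi_genotype,
                "tpi_match_fraction": match,
            }
        )
    return pd.DataFrame(rows)


def calls_long_format(calls: pd.DataFrame) -> pd.DataFrame:
    """Tidy long-format call table: specimen_id,marker,call,detail,match_fraction."""
    rows = []
    for _, r in calls.iterrows():
        rows.append(
            {
                "specimen_id": r["specimen_id"],
                "marker": "sCOIB",
                "call": r["coi_class"],
                "detail": r["combined_class"],
                "match_fraction": 1.0 if r["coi_class"] != "uncallable" else 0.0,
            }
        )
        rows.append(
            {
                "specimen_id": r["specimen_id"],
                "marker": "sTpiI140",
                "call": r["tpi_genotype"],
                "detail": "",
                "match_fraction": r["tpi_match_fraction"],
            }
        )
    return pd.DataFrame(rows)


def fis_report(counts_list: Sequence[GenotypeCounts]) -> pd.DataFrame:
    """Per-collection F_is with Total (pooled) and Mean rows.

    Undefined (monomorphic) collections display "nd" and are skipped in
    the mean; display values are rounded half-up to two decimals.
    """
    if not counts_list:
        raise EmptyCallSetError("no genotype counts supplied")
    rows = []
    for c in counts_list:
        r = fis(c)
        rows.append(_fis_row(c.label or "collection", c, r))
    total = pooled_fis(counts_list)
    total_counts = GenotypeCounts(
        sum(c.n_del_hom for c in counts_list),
        sum(c.n_plus_hom for c in counts_list),
        sum(c.n_het for c in counts_list),
        label="Total",
    )
    rows.append(_fis_row("Total", total_counts, total))
    try:
        mean = mean_fis(counts_list)
        mean_disp = f"{round_half_up(mean, 2):.2f}"
    except ValueError:
        mean, mean_disp = float("nan"), "nd"
    rows.append(
        {
            "collection": "Mean",
            "n_del_hom": "",
            "n_plus_hom": "",
            "n_het": "",
            "fis_full": mean,
            "fis": mean_disp,
        }
    )
    return pd.DataFrame(rows)


def _fis_row(label: str, c: GenotypeCounts, r: FisResult) -> dict:
    return {
        "collection": label,
        "n_del_hom": c.n_del_hom,
        "n_plus_hom": c.n_plus_hom,
        "n_het": c.n_het,
        "fis_full": r.fis if r.defined else float("nan"),
        "fis": f"{round_half_up(r.fis, 2):.2f}" if r.defined else "nd",
    }


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Execute one full run and write the report bundle.

    Returns a dict with the output paths and the in-memory tables. The
    manifest records package version, seed, a config hash, and every
    statistic at full precision next to its display rounding.
    """
    config.validate()
    ref = config.reference or default_reference()
    os.makedirs(config.out_dir, exist_ok=True)
    config_hash = hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()
    log.info(
        "looperpop %s | seed=%d | config sha256=%s",
        __version__,
        config.seed,
        config_hash[:12],
    )

    if config.simulations is not None:
        specimens = []
        rng = np.random.default_rng(config.seed)
        for sim in config.simulations:
            # per-collection streams derived from the run seed unless a
            # collection pins its own
            sim_seed = sim.seed if sim.seed is not None else 0
            derived = int(rng.integers(0, 2**31 - 1))
            sim = replace(sim, seed=(sim_seed if sim_seed else derived))
            specimens.extend(simulate_collection(sim, ref))
        paths = write_dataset(specimens, os.path.join(config.out_dir, "dataset"))
        coi_reads = [(s.specimen_id, s.coi_read) for s in specimens]
        tpi_reads = [(s.specimen_id, s.tpi_read) for s in specimens]
        meta = read_metadata(paths["metadata"])
    else:
        for key in ("coi_fasta", "tpi_fasta", "metadata"):
            p = config.inputs.get(key)
            if p is None or not os.path.exists(p):
                raise MissingInputError(f"missing input {key}: {p}")
        coi_reads = read_fasta(config.inputs["coi_fasta"])
        tpi_reads = read_fasta(config.inputs["tpi_fasta"])
        meta = read_metadata(config.inputs["metadata"])

    calls = call_dataset(coi_reads, tpi_reads, ref, min_match=config.min_match)
    merged = calls.merge(meta, on="specimen_id", how="left")
    merged["sex"] = merged["sex"].fillna("unknown")
    tpi_map = dict(tpi_reads)
    merged["tpi_read"] = merged["specimen_id"].map(tpi_map)
    callable_mask = merged["tpi_genotype"].isin(
        ["del_only", "plus_only", "heterozygous"]
    ) & merged["coi_class"].isin(["T1035", "C1035"])
    if not callable_mask.any():
        raise EmptyCallSetError("no specimen produced callable results at both markers")

    calls_path = os.path.join(config.out_dir, "calls.csv")
    write_calls(calls_long_format(calls), calls_path)

    manifest_stats: List[dict] = []

    def record(name: str, value: float, display: str) -> None:
        manifest_stats.append(
            {"name": name, "value_full": value, "value_display": display}
        )

    # grouped allele frequencies + paired t-test (Table-2C-style)
    freq_rows = del_freq_by_haplotype_group(
        merged[callable_mask], group_by="state", min_per_class=config.min_per_class
    )
    def _pct(x: float) -> float:
        return float(round(x)) if np.isfinite(x) else float("nan")

    freq_df = pd.DataFrame(
        {
            "unit": [r.unit for r in freq_rows],
            "n": [r.n for r in freq_rows],
            "freq_del_in_C1035": [_pct(r.freq_del_in_C1035) for r in freq_rows],
            "freq_del_in_T1035": [_pct(r.freq_del_in_T1035) for r in freq_rows],
        }
    )
    t_result = pearson = None
    if len(freq_rows) >= 2:
        pairs = [(r.freq_del_in_C1035, r.freq_del_in_T1035) for r in freq_rows]
        try:
            t_result = paired_t_test(pairs)
            record("t_del_freq", t_result.t, f"{t_result.t:.3f}")
            record("df_del_freq", t_result.df, str(t_result.df))
            record("p_del_freq", t_result.p_two_sided, f"{t_result.p_two_sided:.3g}")
        except ValueError:
            pass
        mc, sc = column_mean_sd([p[0] for p in pairs])
        mt, st = column_mean_sd([p[1] for p in pairs])
        record("mean_del_in_C1035", mc, f"{round(mc)} ± {round(sc)}")
        record("mean_del_in_T1035", mt, f"{round(mt)} ± {round(st)}")
    if len(freq_rows) >= 3:
        try:
            r, p = pearson_correlation(
                [r.freq_del_in_C1035 for r in freq_rows],
                [r.freq_del_in_T1035 for r in freq_rows],
            )
            pearson = (r, p)
            record("pearson_r", r, f"{r:.3f}")
            record("pearson_p", p, f"{p:.3g}")
        except ValueError:
            pass
    freq_path = os.path.join(config.out_dir, "del_freq_by_haplotype.csv")
    freq_df.to_csv(freq_path, index=False)

    # F_is report (Table-3-style), per collection
    counts_list = []
    for label, grp in merged[callable_mask].groupby("collection", sort=True):
        counts_list.append(genotype_counts_from_calls(grp, label=str(label)))
    counts_list = [c for c in counts_list if c.n > 0]
    if not counts_list:
        raise EmptyCallSetError("no collection with scoreable genotypes")
    fis_df = fis_report(counts_list)
    for _, row in fis_df.iterrows():
        record(f"fis_{row['collection']}", row["fis_full"], str(row["fis"]))
    fis_path = os.path.join(config.out_dir, "fis_report.csv")
    fis_df.to_csv(fis_path, index=False)

    # clan summary (Table-4-style)
    clan_df = clan_marker_summary(
        merged[callable_mask],
        plus_consensus=ref.tpi_plus_consensus,
        del_consensus=ref.tpi_del_consensus,
    )
    clan_path = os.path.join(config.out_dir, "clan_summary.csv")
    clan_df.to_csv(clan_path, index=False)
    for _, row in clan_df.iterrows():
        record(
            f"pct_T1035_clan{row['clan']}",
            float(row["pct_T1035"]),
            f"{row['pct_T1035']:.0f}%" if np.isfinite(row["pct_T1035"]) else "nd",
        )

    manifest = {
        "package": "looperpop",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": config_hash,
        "statistics": manifest_stats,
    }
    manifest_path = os.path.join(config.out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")

    return {
        "calls": calls,
        "freq_rows": freq_rows,
        "fis_report": fis_df,
        "clan_summary": clan_df,
        "paired_t": t_result,
        "pearson": pearson,
        "manifest": manifest,
        "paths": {
            "calls": calls_path,
            "del_freq": freq_path,
            "fis_report": fis_path,
            "clan_summary": clan_path,
            "manifest": manifest_path,
        },
    }
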