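"""Dataset and call-table round-tripping.

A dataset on disk is one FASTA per marker (record id = specimen id)
plus a comma-delimited metadata table with the header
``specimen_id,collection,state,year,type,sex``. Calls are emitted as
``specimen_id,marker,call,detail,match_fraction``.
"""

from __future__ import annotations

import os
from typing import Dict, List, Sequence, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import TrueSpecimen

METADATA_COLUMNS = ["specimen_id", "collection", "state", "year", "type", "sex"]
CALL_COLUMNS = ["specimen_id", "marker", "call", "detail", "match_fraction"]

COI_FASTA = "coi_reads.fasta"
TPI_FASTA = "tpi_reads.fasta"
METADATA_CSV = "metadata.csv"


def write_fasta(records: Sequence[Tuple[str, str]], path: str) -> None:
    """Write (id, sequence) pairs as FASTA; duplicate ids are an error."""
    ids = [r[0] for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate FASTA ids: {dupes}")
    seqrecords = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seqrecords, path, "fasta")


def read_fasta(path: str) -> List[Tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]


def write_dataset(specimens: Sequence[TrueSpecimen], out_dir: str) -> Dict[str, str]:
    """Write a specimen list as FASTA pair + metadata table.

    Returns the paths written. Re-reading reproduces ids, reads and
    metadata bit-exactly. An empty sex field is written for unknown-sex
    specimens.
    """
    if not specimens:
        raise ValueError("empty specimen list")
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "coi_fasta": os.path.join(out_dir, COI_FASTA),
        "tpi_fasta": os.path.join(out_dir, TPI_FASTA),
        "metadata": os.path.join(out_dir, METADATA_CSV),
    }
    write_fasta([(s.specimen_id, s.coi_read) for s in specimens], paths["coi_fasta"])
    write_fasta([(s.specimen_id, s.tpi_read) for s in specimens], paths["tpi_fasta"])
    meta = pd.DataFrame(
        {
            "specimen_id": [s.specimen_id for s in specimens],
            "collection": [s.collection for s in specimens],
            "state": [s.state for s in specimens],
            "year": [s.year for s in specimens],
            "type": [s.collection_type for s in specimens],
            "sex": ["" if s.sex == "unknown" else s.sex for s in specimens],
        }
    )
    meta.to_csv(paths["metadata"], index=False)
    return paths


def read_metadata(path: str) -> pd.DataFrame:
    """Read a metadata table; an empty sex field maps back to 'unknown'."""
    meta = pd.read_csv(path, dtype={"specimen_id": str}, keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    meta["sex"] = meta["sex"].replace("", "unknown")
    return meta


def write_calls(calls: pd.DataFrame, path: str) -> None:
    missing = [c for c in CALL_COLUMNS if c not in calls.columns]
    if missing:
        raise ValueError(f"call table missing columns: {missing}")
    calls[CALL_COLUMNS].to_csv(path, index=False)


def read_calls(path: str) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"specimen_id": str}, keep_default_na=False)
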