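"""File I/O: FASTA, BED, TSV tables and YAML configuration.

Conventions: TSVs are tab-separated UTF-8 with a header row and '.' for
missing values; BED intervals are 0-based half-open; human-facing site
tables use 1-based inclusive coordinates and say so in a header comment.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .calling import CloneCallMatrix, CloneRead, GroupMethylationSummary
from .reference import CpGIsland, CpGSite

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_clones",
    "write_islands_bed",
    "write_sites_tsv",
    "write_call_matrix",
    "write_group_summaries",
    "read_tsv",
    "load_yaml_config",
]

_VALID = set("ACGTN")


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, uppercase sequence) pairs.

    Wrapped lines are joined; duplicate ids, empty files and RNA bases (U)
    are errors.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        bad = set(seq) - _VALID
        if bad:
            raise ValueError(
                f"{path}: record {rec.id!r} contains invalid base(s) "
                f"{sorted(bad)} (RNA input?)"
            )
        records.append((rec.id, seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def write_fasta(path, records: list[tuple[str, str]], width: int = 70) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records],
        str(path),
        "fasta",
    )


def read_clones(fasta_path, manifest_path=None) -> list[CloneRead]:
    """Load clone reads, assigning groups from a manifest TSV
    (clone_id, group_id) or from a ``group|clone`` record-id convention."""
    records = read_fasta(fasta_path)
    if manifest_path is not None:
        manifest = pd.read_csv(manifest_path, sep="\t", dtype=str)
        groups = dict(zip(manifest["clone_id"], manifest["group_id"]))
        missing = [rid for rid, _ in records if rid not in groups]
        if missing:
            raise ValueError(
                f"{manifest_path}: no group for clone(s) {missing[:5]}"
            )
        return [CloneRead(rid, groups[rid], seq) for rid, seq in records]
    reads = []
    for rid, seq in records:
        if "|" not in rid:
            raise ValueError(
                f"clone {rid!r}: no manifest given and id is not 'group|clone'"
            )
        group, clone = rid.split("|", 1)
        reads.append(CloneRead(clone, group, seq))
    return reads


def write_islands_bed(path, ref_id: str, islands: list[CpGIsland]) -> None:
    with open(path, "w") as fh:
        for i, isl in enumerate(islands, 1):
            fh.write(
                f"{ref_id}\t{isl.start}\t{isl.end}\tCGI_{i}\t"
                f"{isl.gc:.4f}\t{isl.obs_exp:.4f}\n"
            )


def write_sites_tsv(path, sites: list[CpGSite]) -> None:
    with open(path, "w") as fh:
        fh.write("# coords=1-based\nsite\tc_position\n")
        for s in sites:
            fh.write(f"{s.index}\t{s.c_position + 1}\n")


def write_call_matrix(path, matrix: CloneCallMatrix) -> None:
    df = matrix.calls.copy()
    df.insert(0, "group_id", matrix.group_id)
    df.to_csv(path, sep="\t")


def write_group_summaries(path, summaries: list[GroupMethylationSummary]) -> None:
    rows = []
    for s in summaries:
        for site in s.per_site_rate.index:
            rate = s.per_site_rate[site]
            rows.append(
                {
                    "group_id": s.group_id,
                    "site": site,
                    "n_valid": int(s.valid_calls[site]),
                    "rate": "." if pd.isna(rate) else f"{rate:.6f}",
                    "integral_rate": f"{s.integral_rate:.6f}",
                    "n_clones": s.n_clones,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["."], comment="#")


def load_yaml_config(path, allowed_keys: set[str]) -> dict:
    """Load a YAML mapping, rejecting unknown keys."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(cfg) - allowed_keys
    if unknown:
        raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
    return cfg
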