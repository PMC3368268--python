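"""Formats, configuration and output headers.

All interval I/O is 0-based half-open (BED convention); the RepeatMasker
``.out`` reader converts its 1-based starts at the boundary.  Every table
written by the pipeline carries a header line naming the tool version, the
config hash and the seed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__, dna

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_fasta(path) -> dict[str, np.ndarray]:
    """FASTA -> {record id: encoded sequence}."""
    return {rec.id: dna.encode(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict[str, np.ndarray | str]) -> None:
    records = [
        SeqRecord(Seq(seq if isinstance(seq, str) else dna.decode(seq)), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_bed(path, extra_columns: list[str] | None = None) -> pd.DataFrame:
    """BED6(+N) -> DataFrame; missing optional columns are filled."""
    cols = BED6_COLUMNS + (extra_columns or [])
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = cols[: df.shape[1]]
    for c, default in (("name", "."), ("score", 0), ("strand", "+")):
        if c not in df.columns:
            df[c] = default
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def write_bed(path, df: pd.DataFrame, extra_columns: list[str] | None = None, meta: dict | None = None) -> None:
    cols = [c for c in BED6_COLUMNS + (extra_columns or []) if c in df.columns]
    out = df.copy()
    for c, default in (("name", "."), ("score", 0), ("strand", "+")):
        if c not in out.columns:
            out[c] = default
            if c in BED6_COLUMNS and c not in cols:
                cols = BED6_COLUMNS + (extra_columns or [])
                cols = [c2 for c2 in cols if c2 in out.columns]
    with open(path, "w") as fh:
        if meta:
            fh.write("# " + "\t".join(f"{k}={v}" for k, v in meta.items()) + "\n")
        out[cols].to_csv(fh, sep="\t", header=False, index=False)


def write_bedgraph(path, values: np.ndarray, bin_size: int, chrom: str = "chr1", meta: dict | None = None) -> None:
    """Per-bin values -> bedGraph lines."""
    with open(path, "w") as fh:
        if meta:
            fh.write("# " + "\t".join(f"{k}={v}" for k, v in meta.items()) + "\n")
        for i, v in enumerate(values):
            fh.write(f"{chrom}\t{i * bin_size}\t{(i + 1) * bin_size}\t{v}\n")


def read_bedgraph(path) -> tuple[np.ndarray, int, str]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", names=["chrom", "start", "end", "value"])
    bin_size = int(df["end"].iloc[0] - df["start"].iloc[0])
    return df["value"].to_numpy(), bin_size, str(df["chrom"].iloc[0])


def read_repeatmasker_out(path) -> pd.DataFrame:
    """RepeatMasker .out -> BED-convention repeat annotation.

    Keeps score, divergence percentage, coordinates (converted to 0-based
    half-open), strand ('C' -> '-'), repeat name and class/family split.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 11 or not parts[0].replace(".", "").isdigit():
                continue
            rclass_family = parts[10]
            rclass, _, family = rclass_family.partition("/")
            rows.append(
                {
                    "chrom": parts[4],
                    "start": int(parts[5]) - 1,
                    "end": int(parts[6]),
                    "strand": "-" if parts[8] in ("C", "-") else "+",
                    "name": parts[9],
                    "class": rclass,
                    "family": family or rclass,
                    "divergence_percent": float(parts[1]),
                }
            )
    return pd.DataFrame(rows)


def load_config_file(path) -> dict:
    """YAML (or flat key=value) configuration -> dict."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
        if isinstance(data, dict):
            return data
    except yaml.YAMLError:
        pass
    out = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or "=" not in line:
            continue
        k, v = line.split("=", 1)
        out[k.strip()] = yaml.safe_load(v.strip())
    return out


def dump_config_file(path, config: dict) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def output_meta(config: dict, seed: int) -> dict:
    return {"tool": f"ctcf-repeatscape/{__version__}", "config": config_hash(config), "seed": seed}


def write_table(path, df: pd.DataFrame, meta: dict | None = None, index: bool = False) -> None:
    with open(path, "w") as fh:
        if meta:
            fh.write("# " + "\t".join(f"{k}={v}" for k, v in meta.items()) + "\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
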