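"""Readers and writers for the standard formats plus raw-read spacer counting.

FASTA via Biopython, BED 0-based half-open via pandas with per-line
validation, MatrixMarket single-cell matrices via scipy into AnnData.
Result TSVs carry a provenance header (tool version, seed, config digest).
"""

from __future__ import annotations

import gzip
import hashlib
import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import io as scipy_io
from scipy import sparse

from . import __version__

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def load_genome(path) -> dict:
    """FASTA -> {name: sequence}, names and order preserved."""
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_genome(sequences: dict, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def load_intervals(path) -> pd.DataFrame:
    """BED (3-6 columns), 0-based half-open, validated with line numbers."""
    rows = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {ln}: fewer than 3 BED fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as err:
                raise ValueError(f"{path}: line {ln}: non-integer coordinates") from err
            if start < 0 or start >= end:
                raise ValueError(f"{path}: line {ln}: require 0 <= start < end")
            name = parts[3] if len(parts) > 3 else ""
            score = parts[4] if len(parts) > 4 else "."
            strand = parts[5] if len(parts) > 5 else "."
            rows.append((parts[0], start, end, name, score, strand))
    return pd.DataFrame(rows, columns=BED_COLUMNS)


def write_intervals(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col, default in (("name", ""), ("score", "."), ("strand", ".")):
        if col not in out:
            out[col] = default
    out[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# MatrixMarket single-cell matrices
# ---------------------------------------------------------------------------

def load_matrix(directory) -> ad.AnnData:
    """Read matrix.mtx + barcodes.tsv + features.tsv into cells x features."""
    directory = Path(directory)
    mat = scipy_io.mmread(directory / "matrix.mtx").tocsr()
    barcodes = pd.read_csv(directory / "barcodes.tsv", sep="\t", header=None)[0]
    features = pd.read_csv(directory / "features.tsv", sep="\t", header=None)
    if mat.shape[0] != len(barcodes):
        raise ValueError(
            f"{directory}: matrix has {mat.shape[0]} rows but {len(barcodes)} barcodes"
        )
    if mat.shape[1] != len(features):
        raise ValueError(
            f"{directory}: matrix has {mat.shape[1]} columns but {len(features)} features"
        )
    obs = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    var = pd.DataFrame(index=pd.Index(features[0], name="feature"))
    for i, col in enumerate(features.columns[1:], start=1):
        var[f"col{i}"] = features[col].to_numpy()
    return ad.AnnData(X=mat, obs=obs, var=var)


def write_matrix(adata: ad.AnnData, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    scipy_io.mmwrite(str(directory / "matrix.mtx"), X)
    pd.Series(adata.obs_names).to_csv(
        directory / "barcodes.tsv", sep="\t", header=False, index=False
    )
    adata.var.reset_index().to_csv(
        directory / "features.tsv", sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# spacer counting from raw reads
# ---------------------------------------------------------------------------

def count_spacers(fastq_paths, manifest: pd.DataFrame):
    """Count screen reads by exact 19-nt variable-region matching.

    A read increments a spacer's count iff exactly one manifest spacer's
    variable region (positions 2-20, dropping the forced 5' G) occurs in
    the read. Reads matching zero or more than one spacer are tallied as
    unassigned / ambiguous; malformed records are skipped and counted.
    Returns (counts Series indexed by sgRNA id, tally dict).
    """
    if manifest["spacer"].duplicated().any():
        raise ValueError("manifest spacers must be unique")
    lookup = {}
    for sid, spacer in zip(manifest["id"], manifest["spacer"]):
        lookup.setdefault(spacer[1:], []).append(sid)
    klen = 19
    counts = pd.Series(0, index=manifest["id"].to_numpy())
    tally = {"assigned": 0, "unassigned": 0, "ambiguous": 0, "malformed": 0}
    for path in ([fastq_paths] if isinstance(fastq_paths, (str, Path)) else fastq_paths):
        with _open_text(path) as fh:
            while True:
                header = fh.readline()
                if not header:
                    break
                seq = fh.readline().rstrip("\n").upper()
                plus = fh.readline()
                qual = fh.readline()
                if not header.startswith("@") or not plus.startswith("+") or not qual:
                    tally["malformed"] += 1
                    continue
                hits = set()
                for i in range(len(seq) - klen + 1):
                    ids = lookup.get(seq[i:i + klen])
                    if ids:
                        hits.update(ids)
                        if len(hits) > 1:
                            break
                if len(hits) == 1:
                    counts[hits.pop()] += 1
                    tally["assigned"] += 1
                elif not hits:
                    tally["unassigned"] += 1
                else:
                    tally["ambiguous"] += 1
    return counts, tally


# ---------------------------------------------------------------------------
# config and provenance
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def config_digest(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def write_tsv(df: pd.DataFrame, path, seed=None, config: dict | None = None,
              index: bool = True) -> None:
    """Write a result TSV with a provenance header."""
    with open(path, "w") as fh:
        fh.write(f"# tilescreen {__version__}")
        if seed is not None:
            fh.write(f" seed={seed}")
        if config is not None:
            fh.write(f" config={config_digest(config)}")
        fh.write("\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)
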