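"""Plain-text interchange formats used at the pipeline boundary.

BEAGLE genotype-likelihood files (marker/allele1/allele2 then three
likelihood columns per individual), tab-separated sample sheets and
phenotype tables, GFF3 (1-based inclusive) and BED (0-based half-open)
gene annotations, outlier lists in both conventions, and JSON
run-manifests.  All coordinates are converted to a single internal
convention (0-based half-open) on input; malformed annotation lines raise
with their line number.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genolik import GLMatrix

__all__ = [
    "write_beagle",
    "read_beagle",
    "write_gff3",
    "read_gff3",
    "write_bed",
    "read_bed",
    "write_outliers",
    "write_manifest",
]


def write_beagle(gl: GLMatrix, path) -> None:
    """Write a GLMatrix as a BEAGLE genotype-likelihood text file.

    Markers are ``chrom_pos``; per-individual triples are likelihoods
    normalised to sum to 1.  Missing entries come out flat (1/3, 1/3, 1/3).
    """
    path = Path(path)
    L, N, _ = gl.logl.shape
    chrom = gl.chrom if gl.chrom is not None else np.repeat("1", L)
    pos = gl.pos if gl.pos is not None else np.arange(1, L + 1)
    samples = gl.sample_ids or [f"Ind{i}" for i in range(N)]
    major = gl.allele_major if gl.allele_major is not None else np.repeat("0", L)
    minor = gl.allele_minor if gl.allele_minor is not None else np.repeat("1", L)

    lik = np.exp(gl.logl)
    lik /= lik.sum(axis=-1, keepdims=True)
    header = ["marker", "allele1", "allele2"]
    for s in samples:
        header.extend([s, s, s])
    with path.open("w") as fh:
        fh.write("\t".join(header) + "\n")
        for i in range(L):
            row = [f"{chrom[i]}_{pos[i]}", str(major[i]), str(minor[i])]
            row.extend(f"{v:.6f}" for v in lik[i].ravel())
            fh.write("\t".join(row) + "\n")


def read_beagle(path) -> GLMatrix:
    """Read a BEAGLE genotype-likelihood file into a GLMatrix.

    Likelihood triples are renormalised to max 0 in log space; triples
    that are exactly flat are flagged missing.
    """
    with open(path) as fh:
        header = fh.readline().split()
    if len(header) < 6 or (len(header) - 3) % 3:
        raise ValueError(
            f"{path}: BEAGLE file needs 3 leading columns plus 3 per individual"
        )
    samples = header[3::3]
    df = pd.read_csv(path, sep=r"\s+", header=None, skiprows=1)
    if df.shape[1] != len(header):
        raise ValueError(f"{path}: data width does not match the header")
    markers = df.iloc[:, 0].astype(str)
    chrom_pos = markers.str.rsplit("_", n=1, expand=True)
    lik = df.iloc[:, 3:].to_numpy(dtype=float).reshape(len(df), -1, 3)
    missing = np.isclose(lik, lik[:, :, :1]).all(axis=2)
    with np.errstate(divide="ignore"):
        logl = np.log(lik)
    logl = logl - logl.max(axis=-1, keepdims=True)
    logl[missing] = 0.0
    return GLMatrix(
        logl=logl,
        missing=missing,
        chrom=chrom_pos[0].to_numpy(),
        pos=chrom_pos[1].astype(int).to_numpy(),
        sample_ids=samples,
        allele_major=df.iloc[:, 1].astype(str).to_numpy(),
        allele_minor=df.iloc[:, 2].astype(str).to_numpy(),
        polarized=True,
    )


def write_gff3(annotation: pd.DataFrame, path) -> None:
    """Write gene intervals (internal 0-based half-open) as GFF3 genes."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for row in annotation.itertuples(index=False):
            attrs = f"ID={row.gene_id}"
            fh.write(
                "\t".join(
                    [
                        str(row.chrom),
                        "trawlscan",
                        "gene",
                        str(row.start + 1),  # GFF3 is 1-based inclusive
                        str(row.end),
                        ".",
                        getattr(row, "strand", "+"),
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff3(path, feature_types: set[str] | None = None) -> pd.DataFrame:
    """Read gene intervals from GFF3 into 0-based half-open coordinates.

    Only rows of the requested feature types (default: gene) are kept.
    Malformed lines raise with their line number.
    """
    feature_types = feature_types or {"gene"}
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, got {len(parts)}"
                )
            if parts[2] not in feature_types:
                continue
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 1 or end < start:
                raise ValueError(f"{path}:{lineno}: invalid interval {start}-{end}")
            gene_id = "NA"
            for field in parts[8].split(";"):
                if field.startswith("ID="):
                    gene_id = field[3:]
                    break
            rows.append(
                {
                    "chrom": parts[0],
                    "start": start - 1,
                    "end": end,
                    "gene_id": gene_id,
                    "strand": parts[6],
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "strand"])


def write_bed(annotation: pd.DataFrame, path) -> None:
    """Write gene intervals as BED (0-based half-open, as stored)."""
    path = Path(path)
    with path.open("w") as fh:
        for row in annotation.itertuples(index=False):
            fh.write(
                "\t".join(
                    [
                        str(row.chrom),
                        str(row.start),
                        str(row.end),
                        str(row.gene_id),
                        "0",
                        getattr(row, "strand", "+"),
                    ]
                )
                + "\n"
            )


def read_bed(path) -> pd.DataFrame:
    """Read a BED interval file (0-based half-open, no conversion needed)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: BED needs at least chrom/start/end"
                )
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or end < start:
                raise ValueError(f"{path}:{lineno}: invalid interval {start}-{end}")
            rows.append(
                {
                    "chrom": parts[0],
                    "start": start,
                    "end": end,
                    "gene_id": parts[3] if len(parts) > 3 else f"iv{lineno}",
                    "strand": parts[5] if len(parts) > 5 else "+",
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "strand"])


def write_outliers(outliers: pd.DataFrame, tsv_path, bed_path) -> None:
    """Write an outlier list as 1-based TSV and 0-based half-open BED."""
    outliers.to_csv(tsv_path, sep="\t", index=False)
    with open(bed_path, "w") as fh:
        for row in outliers.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos - 1}\t{row.pos}\t"
                f"zdaf={row.zdaf:.4f};tail={row.tail}\n"
            )


def write_manifest(manifest: dict, path) -> None:
    """Write the run manifest as deterministic, sorted JSON."""
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialise {type(obj)!r}")
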