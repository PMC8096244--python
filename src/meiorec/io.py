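"""Readers and writers for the pipeline's tab-separated formats.

Genotype tables are 1-based inclusive TSV with columns
``chrom  pos  allele_p1  allele_p2  s1a  s1b  s2a  s2b  s3a  s3b  s4a  s4b``
(values ``P1``/``P2``/``NA``); truth tables are
``event_id  type  spore  start  end``.  Coverage tracks use bedGraph
(0-based half-open); readers fill gaps with zero and reject overlaps, and
the writer merges equal-value runs.  Readers reject malformed data rather
than coerce it.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .simulate import (
    GENO_LABELS,
    NA,
    P1,
    P2,
    STRAND_NAMES,
    CoverageTrack,
    MarkerMap,
    OctadGenotypes,
    TruthTable,
)

_GENO_COLUMNS = ("chrom", "pos", "allele_p1", "allele_p2") + STRAND_NAMES
_CODE_BY_LABEL = {"P1": P1, "P2": P2, "NA": NA}


def write_genotype_table(octad: OctadGenotypes, path: str | Path) -> None:
    """Write an octad as the canonical tab-separated genotype table."""
    m = octad.map
    data = {
        "chrom": [m.chrom] * len(m),
        "pos": m.positions,
        "allele_p1": m.allele_p1,
        "allele_p2": m.allele_p2,
    }
    for i, name in enumerate(STRAND_NAMES):
        data[name] = [GENO_LABELS[int(c)] for c in octad.calls[i]]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_genotype_table(path: str | Path, chrom_length: int | None = None) -> OctadGenotypes:
    """Read and validate a genotype table; round-trips with the writer."""
    try:
        # keep_default_na: the literal string "NA" is a genotype code here
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse genotype table {path}: {exc}") from exc
    strand_cols = [c for c in df.columns if c not in ("chrom", "pos", "allele_p1", "allele_p2")]
    if tuple(df.columns[:4]) != _GENO_COLUMNS[:4]:
        raise FormatError(
            f"genotype table must start with columns {_GENO_COLUMNS[:4]}, got {tuple(df.columns[:4])}"
        )
    if len(strand_cols) != 8:
        raise FormatError(f"genotype table has {len(strand_cols)} strand columns, expected 8")
    if tuple(strand_cols) != STRAND_NAMES:
        raise FormatError(f"strand columns must be {STRAND_NAMES}, got {tuple(strand_cols)}")
    if df["chrom"].nunique() != 1:
        raise FormatError("genotype table must describe a single chromosome")
    pos = df["pos"].astype(np.int64).to_numpy()
    bad = np.flatnonzero(np.diff(pos) <= 0)
    if bad.size:
        raise FormatError(
            f"positions not strictly increasing at row {int(bad[0]) + 3} (pos {pos[bad[0] + 1]})"
        )
    calls = np.empty((8, len(df)), dtype=np.int8)
    for i, name in enumerate(STRAND_NAMES):
        col = df[name]
        unknown = ~col.isin(_CODE_BY_LABEL)
        if unknown.any():
            row = int(np.flatnonzero(unknown)[0]) + 2
            raise FormatError(f"unknown genotype value {col[unknown].iloc[0]!r} at row {row}")
        calls[i] = col.map(_CODE_BY_LABEL).to_numpy(dtype=np.int8)
    marker_map = MarkerMap(
        str(df["chrom"].iloc[0]),
        pos,
        df["allele_p1"].to_numpy(),
        df["allele_p2"].to_numpy(),
        int(chrom_length if chrom_length is not None else pos[-1]),
    )
    return OctadGenotypes(marker_map, calls)


def write_truth_table(truth: TruthTable, path: str | Path) -> None:
    """Write planted events as TSV (event_id, type, spore, start, end)."""
    rows = [
        {
            "event_id": t.event_id,
            "type": t.event_type,
            "spore": t.spore + 1,
            "start": t.start,
            "end": t.end,
        }
        for t in truth.tracts
    ]
    pd.DataFrame(rows, columns=["event_id", "type", "spore", "start", "end"]).to_csv(
        path, sep="\t", index=False
    )


def read_depth_table(path: str | Path) -> tuple[np.ndarray, np.ndarray, MarkerMap]:
    """Read an allele-depth TSV (chrom, pos, strand, n_p1, n_p2).

    Returns (n_p1, n_p2) as 8 x M matrices in strand order plus a marker map
    with placeholder alleles (depth tables carry no allele letters).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "strand", "n_p1", "n_p2"}
    if not required.issubset(df.columns):
        raise FormatError(f"depth table must have columns {sorted(required)}")
    strands = sorted(df["strand"].unique())
    if len(strands) != 8:
        raise FormatError(f"depth table has {len(strands)} strands, expected 8")
    if set(strands) != set(STRAND_NAMES):
        raise FormatError(f"strand names must be {STRAND_NAMES}")
    positions = np.sort(df["pos"].unique()).astype(np.int64)
    m = positions.size
    pos_index = {p: i for i, p in enumerate(positions)}
    n_p1 = np.zeros((8, m))
    n_p2 = np.zeros((8, m))
    strand_index = {name: i for i, name in enumerate(STRAND_NAMES)}
    for _, row in df.iterrows():
        i = strand_index[row["strand"]]
        j = pos_index[row["pos"]]
        n_p1[i, j] = row["n_p1"]
        n_p2[i, j] = row["n_p2"]
    marker_map = MarkerMap(
        str(df["chrom"].iloc[0]),
        positions,
        np.full(m, "A"),
        np.full(m, "B"),
        int(positions[-1]),
    )
    return n_p1, n_p2, marker_map


def read_bedgraph(path: str | Path, chrom_sizes: dict[str, int], step: int = 1) -> CoverageTrack:
    """Read a single-chromosome bedGraph into a fixed-step track.

    Gaps read back as 0; overlapping intervals or intervals beyond the
    chromosome end raise a format error.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=["chrom", "start", "end", "value"]
    )
    if df.empty:
        raise FormatError(f"bedGraph {path} is empty")
    if df["chrom"].nunique() != 1:
        raise FormatError("bedGraph must describe a single chromosome")
    chrom = str(df["chrom"].iloc[0])
    if chrom not in chrom_sizes:
        raise FormatError(f"unknown chromosome {chrom!r}")
    size = chrom_sizes[chrom]
    df = df.sort_values("start").reset_index(drop=True)
    if (df["end"] <= df["start"]).any():
        raise FormatError("bedGraph intervals must have end > start")
    if int(df["end"].max()) > size:
        raise FormatError(f"interval beyond chromosome end ({int(df['end'].max())} > {size})")
    if (df["start"].to_numpy()[1:] < df["end"].to_numpy()[:-1]).any():
        raise FormatError("overlapping bedGraph intervals")
    if size % step:
        raise FormatError("chromosome size must be a multiple of the step")
    values = np.zeros(size // step)
    for start, end, value in df[["start", "end", "value"]].itertuples(index=False):
        if start % step or end % step:
            raise FormatError("bedGraph intervals must align to the step grid")
        values[start // step : end // step] = value
    return CoverageTrack(chrom, values, step, "raw", ("raw",))


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a track as bedGraph, merging runs of equal value."""
    v = track.values
    change = np.flatnonzero(np.diff(v) != 0) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [v.size]])
    with open(path, "w") as fh:
        for s, e in zip(starts, ends):
            fh.write(f"{track.chrom}\t{s * track.step}\t{e * track.step}\t{v[s]:g}\n")


def file_digest(path: str | Path) -> str:
    """Short SHA-256 digest of a file, for run metadata."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]
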