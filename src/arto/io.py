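"""Probe-table input and genomic-format output.

Replication-timing (ToR) measurements arrive as tab-delimited per-probe
tables (chromosome, position, normalized S/G1 ratio).  Fitted maps are
exported as BED6 (one record per CTR/TTR segment), bedGraph (per-probe
fitted ToR) and a per-probe annotation TSV.

Coordinate convention: input positions are 1-based probe midpoints; each
probe is exported with a fixed single-bp footprint of ``[pos-1, pos)`` in
0-based half-open BED space, so the mapping is exactly invertible.  Array
probe lengths are not modeled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("arto")

DEFAULT_COLUMNS = {"chromosome": "chromosome", "position": "position", "value": "value"}


@dataclass
class ProbeSignal:
    """Ordered per-chromosome probe positions with normalized S/G1 values.

    Positions are 1-based bp probe midpoints, strictly increasing; values
    are dimensionless S/G1 ratios (raw arrays span roughly 1-2, early
    loci high, late loci low).
    """

    chromosome: str
    positions: np.ndarray
    values: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.positions.shape != self.values.shape:
            raise ValueError("positions and values must have equal length")
        if len(self.positions) < 2:
            raise ValueError("a ProbeSignal needs at least 2 probes")
        if not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def value_range(self) -> float:
        return float(self.values.max() - self.values.min())


@dataclass
class GenomicRegion:
    """Half-open genomic interval ``[start, end)`` (0-based), e.g. a gene."""

    chromosome: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid region {self.chromosome}:{self.start}-{self.end}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start


def read_probe_table(path, column_map: dict | None = None, sample_id: str = "",
                     sep: str = "\t") -> dict[str, ProbeSignal]:
    """Read a per-probe ToR table into one :class:`ProbeSignal` per chromosome.

    Probes are sorted by position, duplicate positions are collapsed by
    mean, and rows with missing values are dropped (count logged).
    Chromosomes with fewer than 2 surviving probes are excluded with a
    warning.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    try:
        df = pd.read_csv(path, sep=sep, usecols=list(cols.values()),
                         dtype={cols["chromosome"]: str})
    except ValueError as exc:
        raise ValueError(f"cannot parse probe table {path}: {exc}") from exc
    df = df.rename(columns={v: k for k, v in cols.items()})
    df["position"] = pd.to_numeric(df["position"], errors="raise")
    df["value"] = pd.to_numeric(df["value"], errors="coerce")

    n_missing = int(df["value"].isna().sum() + df["position"].isna().sum())
    if n_missing:
        logger.info("dropped %d rows with missing values from %s", n_missing, path)
    df = df.dropna(subset=["position", "value"])

    signals: dict[str, ProbeSignal] = {}
    for chrom, grp in df.groupby("chromosome", sort=False):
        grp = grp.groupby("position", as_index=False)["value"].mean().sort_values("position")
        if len(grp) < 2:
            logger.warning("chromosome %s has <2 probes after filtering; excluded", chrom)
            continue
        signals[str(chrom)] = ProbeSignal(
            chromosome=str(chrom),
            positions=grp["position"].to_numpy(np.int64),
            values=grp["value"].to_numpy(np.float64),
            sample_id=sample_id,
        )
    return signals


def write_probe_table(signals: dict[str, ProbeSignal] | ProbeSignal, path,
                      sep: str = "\t") -> None:
    """Write ProbeSignals back to a tab-delimited probe table."""
    if isinstance(signals, ProbeSignal):
        signals = {signals.chromosome: signals}
    frames = [
        pd.DataFrame({"chromosome": s.chromosome, "position": s.positions, "value": s.values})
        for s in signals.values()
    ]
    pd.concat(frames).to_csv(path, sep=sep, index=False)


def _segment_bed_records(result) -> list[tuple[int, int, str, int]]:
    # Segment [a, b] in probe-midpoint space maps to BED [round(a)-1, round(b))
    # for the first segment of a block and [prev_end, round(b)) afterwards,
    # so records tile without overlap under the [pos-1, pos) footprint rule.
    fitted_min = float(result.fitted.min())
    span = float(result.fitted.max() - fitted_min)
    records = []
    prev_end = None
    prev_block = None
    for i in range(result.n_segments):
        a, b = result.seg_start_x[i], result.seg_end_x[i]
        block = result.seg_block[i]
        start = int(round(a)) - 1 if (prev_end is None or block != prev_block) else prev_end
        end = int(round(b))
        in_seg = (result.positions >= a) & (result.positions <= b)
        mean_tor = float(result.fitted[in_seg].mean()) if in_seg.any() else float(
            0.5 * (result.seg_start_v[i] + result.seg_end_v[i]))
        score = 0 if span == 0 else int(round(1000 * (mean_tor - fitted_min) / span))
        records.append((start, end, str(result.seg_type[i]), score))
        prev_end, prev_block = end, block
    return records


def write_segments_bed(result, path) -> None:
    """Export a segmentation as BED6: one record per segment.

    The name field encodes the activity type (``CTR``/``TTR``), the score
    the segment's mean fitted ToR rescaled to 0-1000.
    """
    if result.n_segments == 0:
        raise ValueError("cannot write an empty segmentation")
    with open(path, "w") as fh:
        for i, (start, end, typ, score) in enumerate(_segment_bed_records(result)):
            fh.write(f"{result.chromosome}\t{start}\t{end}\t{typ}_{i + 1}\t{score}\t.\n")


def write_fitted_bedgraph(result, path) -> None:
    """Export per-probe fitted ToR as bedGraph with [pos-1, pos) footprints."""
    if result.n_segments == 0:
        raise ValueError("cannot write an empty segmentation")
    with open(path, "w") as fh:
        for pos, val in zip(result.positions, result.fitted):
            fh.write(f"{result.chromosome}\t{pos - 1}\t{pos}\t{val:.6f}\n")


def read_fitted_bedgraph(path) -> dict[str, ProbeSignal]:
    """Read back a bedGraph written by :func:`write_fitted_bedgraph`."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chromosome", "start", "end", "value"],
                     dtype={"chromosome": str})
    out = {}
    for chrom, grp in df.groupby("chromosome", sort=False):
        out[str(chrom)] = ProbeSignal(str(chrom), grp["end"].to_numpy(np.int64),
                                      grp["value"].to_numpy(np.float64))
    return out


def read_regions_bed(path) -> list[GenomicRegion]:
    """Read BED intervals (first 3-4 columns) as GenomicRegions."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    regions = []
    for row in df.itertuples(index=False):
        name = str(row[3]) if len(row) > 3 else ""
        regions.append(GenomicRegion(str(row[0]), int(row[1]), int(row[2]), name))
    return regions


def write_annotation_tsv(annotations: pd.DataFrame, path) -> None:
    annotations.to_csv(path, sep="\t", index=False)
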