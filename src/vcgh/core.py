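"""Shared domain containers: genome annotation, expression/symbol/CNA matrices, segments.

Every matrix in the pipeline shares one probe ordering, defined by the
:class:`GenomeAnnotation` it was built against.  Coordinates are 0-based
half-open throughout, matching BED.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SYMBOLS = ("H", "L", "M")
LABELS = ("+", "-", "o")

GAIN, LOSS, NEUTRAL = "+", "-", "o"


def natural_chrom_key(chrom: str):
    """Sort key placing chr2 before chr10 and autosomes before X/Y."""
    m = re.match(r"(?:chr)?(\d+)$", chrom)
    if m:
        return (0, int(m.group(1)), "")
    return (1, 0, chrom)


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class Probe:
    probe_id: str
    chrom: str
    start: int
    end: int
    cytoband: str


class GenomeAnnotation:
    """Ordered probes with coordinates and cytoband membership.

    The probe order — chromosomes in natural order, probes by start (ties by
    probe_id) — is the chain order of every per-chromosome HMM.  Cytobands
    must partition each chromosome's probes into contiguous runs.
    """

    def __init__(self, table: pd.DataFrame):
        required = ["probe_id", "chrom", "start", "end", "cytoband"]
        missing = [c for c in required if c not in table.columns]
        if missing:
            raise AnnotationError(f"annotation missing columns: {missing}")
        df = table[required].copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        bad = df["start"] >= df["end"]
        if bad.any():
            pid = df.loc[bad, "probe_id"].iloc[0]
            raise AnnotationError(f"probe {pid!r}: start >= end")
        if df["probe_id"].duplicated().any():
            dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise AnnotationError(f"duplicate probe_id {dup!r}")
        df["_ckey"] = df["chrom"].map(natural_chrom_key)
        df = df.sort_values(["_ckey", "start", "probe_id"], kind="mergesort")
        df = df.drop(columns="_ckey").reset_index(drop=True)
        self.table = df
        self.probe_ids = df["probe_id"].to_numpy()
        self._probe_pos = {p: i for i, p in enumerate(self.probe_ids)}
        # per-chromosome contiguous index ranges
        self.chrom_slices: dict[str, slice] = {}
        for chrom, grp in df.groupby("chrom", sort=False):
            idx = grp.index.to_numpy()
            self.chrom_slices[chrom] = slice(int(idx[0]), int(idx[-1]) + 1)
        self._check_cytoband_contiguity()

    def _check_cytoband_contiguity(self):
        self.cytoband_slices: dict[tuple[str, str], slice] = {}
        for chrom, sl in self.chrom_slices.items():
            sub = self.table.iloc[sl]
            seen: set[str] = set()
            prev = None
            start = sl.start
            for i, band in zip(sub.index, sub["cytoband"]):
                if band != prev:
                    if prev is not None:
                        self.cytoband_slices[(chrom, prev)] = slice(start, i)
                    if band in seen:
                        raise AnnotationError(
                            f"cytoband {band!r} on {chrom} is not a contiguous probe run"
                        )
                    seen.add(band)
                    prev, start = band, i
            self.cytoband_slices[(chrom, prev)] = slice(start, sl.stop)

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_slices)

    @property
    def n_probes(self) -> int:
        return len(self.table)

    def probe_index(self, probe_id: str) -> int:
        return self._probe_pos[probe_id]

    def midpoints(self) -> np.ndarray:
        return (self.table["start"].to_numpy() + self.table["end"].to_numpy()) // 2

    def cytobands_on(self, chrom: str) -> list[str]:
        return [b for (c, b) in self.cytoband_slices if c == chrom]

    def __len__(self) -> int:
        return self.n_probes

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeAnnotation) and self.table.equals(other.table)


class _AlignedMatrix:
    """Probes x samples matrix aligned to a GenomeAnnotation."""

    def __init__(self, values: np.ndarray, annotation: GenomeAnnotation,
                 sample_ids: list[str]):
        values = np.asarray(values)
        if values.shape != (annotation.n_probes, len(sample_ids)):
            raise ValueError(
                f"matrix shape {values.shape} does not match "
                f"({annotation.n_probes} probes, {len(sample_ids)} samples)"
            )
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample_ids")
        self.values = values
        self.annotation = annotation
        self.sample_ids = list(sample_ids)

    @property
    def probe_ids(self) -> np.ndarray:
        return self.annotation.probe_ids

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def column(self, sample_id: str, chrom: str | None = None) -> np.ndarray:
        col = self.values[:, self.sample_index(sample_id)]
        if chrom is not None:
            col = col[self.annotation.chrom_slices[chrom]]
        return col


class ExpressionMatrix(_AlignedMatrix):
    """Linear-scale positive intensities, probes x samples."""

    def __init__(self, values, annotation, sample_ids, scale: str = "linear"):
        super().__init__(np.asarray(values, dtype=float), annotation, sample_ids)
        if scale not in ("linear", "log2"):
            raise ValueError(f"unknown scale {scale!r}")
        self.scale = scale
        if scale == "linear" and not (self.values > 0).all():
            i, j = np.argwhere(~(self.values > 0))[0]
            raise ValueError(
                f"non-positive intensity at probe {self.probe_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r} (linear scale requires values > 0)"
            )

    def subset_samples(self, keep: list[str]) -> "ExpressionMatrix":
        idx = [self.sample_index(s) for s in keep]
        return ExpressionMatrix(self.values[:, idx], self.annotation, keep, self.scale)


class SymbolMatrix(_AlignedMatrix):
    """Discretized expression: symbols in {H, L, M}."""

    def __init__(self, symbols, annotation, sample_ids):
        symbols = np.asarray(symbols, dtype="<U1")
        super().__init__(symbols, annotation, sample_ids)
        bad = ~np.isin(symbols, SYMBOLS)
        if bad.any():
            raise ValueError(f"invalid symbol {symbols[bad][0]!r}")


class CnaMatrix(_AlignedMatrix):
    """Copy-number labels in {+, -, o} — truth or prediction."""

    def __init__(self, labels, annotation, sample_ids):
        labels = np.asarray(labels, dtype="<U1")
        super().__init__(labels, annotation, sample_ids)
        bad = ~np.isin(labels, LABELS)
        if bad.any():
            raise ValueError(f"invalid CNA label {labels[bad][0]!r}")


@dataclass(frozen=True)
class Segment:
    chrom: str
    start: int
    end: int
    label: str  # "+" or "-"

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"segment start {self.start} >= end {self.end}")
        if self.label not in (GAIN, LOSS):
            raise ValueError(f"segment label must be + or -, got {self.label!r}")


@dataclass
class SegmentSet:
    """Per-sample gain/loss genomic segments; the genome is normal outside them.

    Same-label overlapping or abutting segments are merged on construction.
    """

    segments: dict[str, list[Segment]] = field(default_factory=dict)

    def __post_init__(self):
        self.segments = {
            s: self._normalize(segs) for s, segs in self.segments.items()
        }

    @staticmethod
    def _normalize(segs: list[Segment]) -> list[Segment]:
        out: list[Segment] = []
        keyed = sorted(segs, key=lambda g: (natural_chrom_key(g.chrom), g.label,
                                            g.start, g.end))
        for seg in keyed:
            if (out and out[-1].chrom == seg.chrom and out[-1].label == seg.label
                    and seg.start <= out[-1].end):
                prev = out.pop()
                seg = Segment(seg.chrom, prev.start, max(prev.end, seg.end), seg.label)
            out.append(seg)
        return sorted(out, key=lambda g: (natural_chrom_key(g.chrom), g.start, g.label))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.segments)

    def for_sample(self, sample_id: str) -> list[Segment]:
        return self.segments.get(sample_id, [])

    def n_segments(self) -> int:
        return sum(len(v) for v in self.segments.values())
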