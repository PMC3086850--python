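"""Discretization of continuous expression and CGH segments.

Expression is trichotomized by fold change against the per-probe cohort
median (default 1.5-fold), CGH tumor/normal ratios by the 1.25/0.75
thresholds.  Boundary values fall in the neutral class: the inequalities
are strict on both sides.
"""

from __future__ import annotations

from dataclasses import dataclass

import logging
import numpy as np

from .core import (
    GAIN, LOSS, NEUTRAL, CnaMatrix, ExpressionMatrix, GenomeAnnotation,
    SegmentSet, SymbolMatrix,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiscretizationConfig:
    fold_threshold: float = 1.5
    gain_ratio: float = 1.25
    loss_ratio: float = 0.75

    def __post_init__(self):
        if not self.fold_threshold > 1:
            raise ValueError("fold_threshold must be > 1")
        if not self.loss_ratio < 1 < self.gain_ratio:
            raise ValueError("need loss_ratio < 1 < gain_ratio")


def probe_medians(expr: ExpressionMatrix) -> np.ndarray:
    """Per-probe cohort medians, on the matrix's own scale."""
    return np.median(expr.values, axis=1)


def symbolize(expr: ExpressionMatrix,
              cfg: DiscretizationConfig = DiscretizationConfig(),
              medians: np.ndarray | None = None) -> SymbolMatrix:
    """Convert intensities to {H, L, M} by fold change vs the probe median.

    *medians* overrides the cohort medians — used in cross-validation to
    symbolize a held-out sample against training-cohort medians only.
    """
    if medians is None:
        medians = probe_medians(expr)
    medians = np.asarray(medians, dtype=float)
    if expr.scale == "linear":
        if not (medians > 0).all():
            i = int(np.argwhere(~(medians > 0))[0][0])
            raise ValueError(
                f"probe {expr.probe_ids[i]!r}: non-positive cohort median")
        ratio = expr.values / medians[:, None]
    else:  # log2 values: ratio = 2**(value - median)
        ratio = np.exp2(expr.values - medians[:, None])
    out = np.full(expr.shape, "M", dtype="<U1")
    out[ratio > cfg.fold_threshold] = "H"
    out[ratio < 1.0 / cfg.fold_threshold] = "L"
    return SymbolMatrix(out, expr.annotation, expr.sample_ids)


def label_ratio(ratio: float,
                cfg: DiscretizationConfig = DiscretizationConfig()) -> str:
    """Map a tumor/normal signal ratio to +, - or o (strict thresholds)."""
    if not ratio > 0:
        raise ValueError(f"non-positive signal ratio {ratio}")
    if ratio > cfg.gain_ratio:
        return GAIN
    if ratio < cfg.loss_ratio:
        return LOSS
    return NEUTRAL


def project_segments(segs: SegmentSet, ann: GenomeAnnotation,
                     sample_ids: list[str] | None = None) -> CnaMatrix:
    """Mark each probe with the label of the segment containing its midpoint.

    When opposite-label segments overlap a probe's midpoint, the segment
    with the larger bp-overlap with the probe wins; an exact tie gives "o".
    """
    if sample_ids is None:
        sample_ids = segs.sample_ids
    mids = ann.midpoints()
    starts = ann.table["start"].to_numpy()
    ends = ann.table["end"].to_numpy()
    out = np.full((ann.n_probes, len(sample_ids)), NEUTRAL, dtype="<U1")
    for j, sample in enumerate(sample_ids):
        # per-probe best (overlap, label) among midpoint-containing segments
        best_overlap = np.zeros(ann.n_probes)
        tie = np.zeros(ann.n_probes, dtype=bool)
        for seg in segs.for_sample(sample):
            if seg.chrom not in ann.chrom_slices:
                log.warning("segment chromosome %r absent from annotation; "
                            "skipped", seg.chrom)
                continue
            sl = ann.chrom_slices[seg.chrom]
            idx = np.arange(sl.start, sl.stop)
            hit = idx[(mids[sl] >= seg.start) & (mids[sl] < seg.end)]
            if hit.size == 0:
                continue
            ov = (np.minimum(ends[hit], seg.end)
                  - np.maximum(starts[hit], seg.start)).clip(min=0)
            better = ov > best_overlap[hit]
            equal = (ov == best_overlap[hit]) & (out[hit, j] != seg.label) \
                & (best_overlap[hit] > 0)
            out[hit[better], j] = seg.label
            best_overlap[hit[better]] = ov[better]
            tie[hit[better]] = False
            tie[hit[equal]] = True
        out[tie, j] = NEUTRAL
    return CnaMatrix(out, ann, list(sample_ids))
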