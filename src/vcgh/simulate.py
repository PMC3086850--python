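"""Synthetic paired expression/CGH cohort generator.

Emulates the data regime the predictor is built for: a tumor cohort where
each chromosome carries zero or more recurrent CNA hotspots, each present
in a given fraction of samples as one contiguous segment whose boundaries
jitter around a block of cytobands, and where copy number couples to
expression through a dosage effect — a probe inside a gain is over-expressed
by ``dosage_effect`` (under-expressed by its reciprocal in a loss) with
probability ``concordance``, on top of multiplicative log-normal noise.

The default preset imitates a diffuse large B-cell lymphoma-like profile
qualitatively: a handful of hotspots recurring in 20-30% of samples, gains
on two chromosomes and losses on two others.  The frequencies and effect
sizes are this package's own realistic choices, not measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    GAIN, LOSS, CnaMatrix, ExpressionMatrix, GenomeAnnotation, Segment,
    SegmentSet,
)
from .discretize import project_segments

PROBE_LEN = 1_000
PROBE_PITCH = 2_000


@dataclass(frozen=True)
class ChromSpec:
    name: str
    n_probes: int
    probes_per_cytoband: int = 10


@dataclass(frozen=True)
class Hotspot:
    """A recurrent CNA: a block of cytobands [band_start, band_end] (indices
    into the chromosome's band list) present with a population frequency."""

    chrom: str
    label: str            # "+" or "-"
    band_start: int
    band_end: int         # inclusive
    frequency: float

    def __post_init__(self):
        if not 0 <= self.frequency <= 1:
            raise ValueError("hotspot frequency must lie in [0, 1]")
        if self.label not in (GAIN, LOSS):
            raise ValueError("hotspot label must be + or -")
        if self.band_start > self.band_end:
            raise ValueError("band_start > band_end")


@dataclass
class CohortConfig:
    n_samples: int = 100
    chromosomes: list[ChromSpec] = field(default_factory=lambda: [
        ChromSpec("chr1", 400, 40), ChromSpec("chr2", 400, 40),
        ChromSpec("chr3", 400, 40), ChromSpec("chr4", 400, 40),
    ])
    hotspots: list[Hotspot] = field(default_factory=lambda: [
        Hotspot("chr1", GAIN, 3, 5, 0.30),
        Hotspot("chr2", GAIN, 5, 7, 0.25),
        Hotspot("chr3", LOSS, 2, 4, 0.25),
        Hotspot("chr4", LOSS, 4, 6, 0.20),
    ])
    dosage_effect: float = 2.0   # linear-scale fold change under a gain
    concordance: float = 0.7     # P(probe in a CNA expresses the dosage)
    noise_sd: float = 0.3        # sd of ln-scale multiplicative noise
    segment_jitter_probes: int = 20  # breakpoint scatter, ~half a cytoband
    baseline_log_mean: float = np.log(100.0)
    baseline_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not self.dosage_effect > 1:
            raise ValueError("dosage_effect must be > 1")
        if not 0 <= self.concordance <= 1:
            raise ValueError("concordance must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        by_chrom: dict[str, list[Hotspot]] = {}
        for h in self.hotspots:
            by_chrom.setdefault(h.chrom, []).append(h)
        for chrom, hs in by_chrom.items():
            for i, a in enumerate(hs):
                for b in hs[i + 1:]:
                    if (a.label != b.label
                            and a.band_start <= b.band_end
                            and b.band_start <= a.band_end):
                        raise ValueError(
                            f"overlapping opposite-label hotspots on {chrom}")


def _band_name(j: int, n_bands: int) -> str:
    """Karyotype-flavored names: p-arm bands count down to the centromere."""
    half = n_bands // 2
    return f"p{half - j}" if j < half else f"q{j - half + 1}"


def build_annotation(cfg: CohortConfig) -> GenomeAnnotation:
    rows = []
    for spec in cfg.chromosomes:
        n_bands = -(-spec.n_probes // spec.probes_per_cytoband)
        for i in range(spec.n_probes):
            start = i * PROBE_PITCH
            rows.append({
                "probe_id": f"{spec.name}_p{i:04d}",
                "chrom": spec.name,
                "start": start,
                "end": start + PROBE_LEN,
                "cytoband": _band_name(i // spec.probes_per_cytoband, n_bands),
            })
    return GenomeAnnotation(pd.DataFrame(rows))


def _hotspot_probe_span(cfg: CohortConfig, spec: ChromSpec,
                        h: Hotspot) -> tuple[int, int]:
    """Ideal [first, last] probe index (within the chromosome) of a hotspot."""
    first = h.band_start * spec.probes_per_cytoband
    last = min((h.band_end + 1) * spec.probes_per_cytoband, spec.n_probes) - 1
    return first, last


def generate(cfg: CohortConfig) -> tuple[ExpressionMatrix, SegmentSet,
                                         GenomeAnnotation, CnaMatrix]:
    """Draw one cohort: (expression, CGH segments, annotation, truth labels)."""
    rng = np.random.default_rng(cfg.seed)
    ann = build_annotation(cfg)
    specs = {s.name: s for s in cfg.chromosomes}
    sample_ids = [f"S{j:03d}" for j in range(cfg.n_samples)]

    segments: dict[str, list[Segment]] = {s: [] for s in sample_ids}
    for sid in sample_ids:
        for h in cfg.hotspots:
            if rng.random() >= h.frequency:
                continue
            spec = specs[h.chrom]
            first, last = _hotspot_probe_span(cfg, spec, h)
            j = cfg.segment_jitter_probes
            if j > 0:
                first = int(np.clip(first + rng.integers(-j, j + 1),
                                    0, spec.n_probes - 1))
                last = int(np.clip(last + rng.integers(-j, j + 1),
                                   first, spec.n_probes - 1))
            segments[sid].append(Segment(
                h.chrom, first * PROBE_PITCH,
                last * PROBE_PITCH + PROBE_LEN, h.label))
    segset = SegmentSet(segments)
    truth = project_segments(segset, ann, sample_ids=sample_ids)

    baseline = np.exp(rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd,
                                 size=ann.n_probes))
    values = np.tile(baseline[:, None], (1, cfg.n_samples))
    in_gain = truth.values == GAIN
    in_loss = truth.values == LOSS
    concordant = rng.random(values.shape) < cfg.concordance
    values[in_gain & concordant] *= cfg.dosage_effect
    values[in_loss & concordant] /= cfg.dosage_effect
    if cfg.noise_sd > 0:
        values *= np.exp(rng.normal(0.0, cfg.noise_sd, size=values.shape))
    expr = ExpressionMatrix(values, ann, sample_ids)
    return expr, segset, ann, truth


def summarize(truth: CnaMatrix, ann: GenomeAnnotation) -> pd.DataFrame:
    """Per-cytoband count of samples harboring a gain / loss."""
    rows = []
    for (chrom, band), sl in ann.cytoband_slices.items():
        sub = truth.values[sl]
        rows.append({
            "chrom": chrom, "cytoband": band,
            "gain": int((sub == GAIN).any(axis=0).sum()),
            "loss": int((sub == LOSS).any(axis=0).sum()),
        })
    return pd.DataFrame(rows)
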