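"""Cytoband-level smoothing via the multinomial log-of-odds (LOD) score.

For each cytoband and sample, probe-label counts (n+, n-, no) are compared
against the sample's whole-genome label counts (N+, N-, No) by the log10
ratio of two multinomial likelihoods: the alternative uses the cytoband's
own MLE proportions, the null the genome background.  Multinomial
coefficients cancel.  A cytoband is called a gain or loss when the LOD
reaches the cutoff (default 2) and the corresponding probe label holds a
strict majority over the opposite one.

Also hosts the two expression-only baselines: rGEP (symbol-to-label
relabeling H->+, L->-, M->o) and sGEP (rGEP followed by LOD smoothing).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .core import GAIN, LOSS, NEUTRAL, CnaMatrix, GenomeAnnotation, SymbolMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CytobandCounts:
    cytoband: str
    n_plus: int
    n_minus: int
    n_o: int
    N_plus: int
    N_minus: int
    N_o: int

    @property
    def n(self) -> int:
        return self.n_plus + self.n_minus + self.n_o

    @property
    def N(self) -> int:
        return self.N_plus + self.N_minus + self.N_o


@dataclass(frozen=True)
class CytobandCall:
    chrom: str
    cytoband: str
    n_plus: int
    n_minus: int
    n_o: int
    lod: float
    call: str  # "+", "-" or "none"


def lod(counts: CytobandCounts) -> float:
    """LOD = sum_j n_j log10(theta1_j / theta0_j), with 0*log(.) = 0.

    theta1 is the cytoband MLE (n_j / n), theta0 the genome background
    (N_j / N).  Non-negative by construction (theta1 maximizes the
    cytoband likelihood).  Background missing a label the cytoband shows
    yields +inf with a warning.
    """
    n = np.array([counts.n_plus, counts.n_minus, counts.n_o], dtype=float)
    N = np.array([counts.N_plus, counts.N_minus, counts.N_o], dtype=float)
    if counts.n < 1:
        raise ValueError("cytoband has no probes")
    if counts.N < counts.n:
        raise ValueError("background smaller than cytoband")
    theta1 = n / counts.n
    theta0 = N / counts.N
    score = 0.0
    for j in range(3):
        if n[j] == 0:
            continue
        if theta0[j] == 0:
            warnings.warn(
                f"cytoband {counts.cytoband!r}: background lacks a label the "
                "cytoband shows; LOD is infinite", RuntimeWarning)
            return float("inf")
        score += n[j] * np.log10(theta1[j] / theta0[j])
    return max(score, 0.0)  # clamp away -0.0 / rounding below machine eps


def call_cytobands(labels: np.ndarray, ann: GenomeAnnotation,
                   lod_cutoff: float = 2.0) -> list[CytobandCall]:
    """Aggregate one sample's per-probe labels into cytoband calls.

    *labels* is a full-genome label column aligned to *ann*.  The
    background is the same column's whole-genome tally.
    """
    labels = np.asarray(labels, dtype="<U1")
    if labels.shape != (ann.n_probes,):
        raise ValueError("label column does not match annotation")
    Np = int((labels == GAIN).sum())
    Nm = int((labels == LOSS).sum())
    No = int((labels == NEUTRAL).sum())
    out: list[CytobandCall] = []
    for (chrom, band), sl in ann.cytoband_slices.items():
        sub = labels[sl]
        if sub.size == 0:
            log.info("cytoband %s %s has no probes; skipped", chrom, band)
            continue
        np_, nm, no = (int((sub == GAIN).sum()), int((sub == LOSS).sum()),
                       int((sub == NEUTRAL).sum()))
        score = lod(CytobandCounts(band, np_, nm, no, Np, Nm, No))
        call = "none"
        if score >= lod_cutoff:
            if np_ > nm:
                call = GAIN
            elif nm > np_:
                call = LOSS
        out.append(CytobandCall(chrom, band, np_, nm, no, score, call))
    return out


def rgep(symbols: SymbolMatrix) -> CnaMatrix:
    """Raw-GEP baseline: H -> +, L -> -, M -> o, elementwise."""
    mapping = {"H": GAIN, "L": LOSS, "M": NEUTRAL}
    out = np.vectorize(mapping.get)(symbols.values).astype("<U1")
    return CnaMatrix(out, symbols.annotation, symbols.sample_ids)


def cytoband_calls_to_labels(calls: list[CytobandCall],
                             ann: GenomeAnnotation) -> np.ndarray:
    """Broadcast cytoband calls back onto the probes of each called band."""
    out = np.full(ann.n_probes, NEUTRAL, dtype="<U1")
    for c in calls:
        if c.call != "none":
            out[ann.cytoband_slices[(c.chrom, c.cytoband)]] = c.call
    return out


def sgep(symbols: SymbolMatrix, ann: GenomeAnnotation,
         lod_cutoff: float = 2.0) -> list[list[CytobandCall]]:
    """Smoothed-GEP baseline: cytoband LOD calls on rGEP labels, per sample."""
    raw = rgep(symbols)
    return [call_cytobands(raw.values[:, j], ann, lod_cutoff)
            for j in range(len(symbols.sample_ids))]


def sgep_matrix(symbols: SymbolMatrix, ann: GenomeAnnotation,
                lod_cutoff: float = 2.0) -> CnaMatrix:
    """sGEP as a probe-level matrix (cytoband calls broadcast to probes)."""
    cols = [cytoband_calls_to_labels(calls, ann)
            for calls in sgep(symbols, ann, lod_cutoff)]
    return CnaMatrix(np.stack(cols, axis=1), ann, symbols.sample_ids)
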