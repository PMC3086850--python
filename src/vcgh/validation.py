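"""Contingency metrics, leave-one-out cross-validation, frequency correlation.

LOOCV holds out one sample at a time: the remaining cohort defines the
per-probe reference medians and trains one HMM per chromosome on composed
symbol/CNA paths; the held-out sample is symbolized against the training
medians and decoded with only its expression.  Gain and loss are scored
separately from one-vs-rest 2x2 tables; fold statistics are aggregated as
mean +/- sd across held-out samples, with undefined metrics (empty
denominators) excluded rather than imputed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    GAIN, LOSS, NEUTRAL, CnaMatrix, ExpressionMatrix, GenomeAnnotation,
    SegmentSet, SymbolMatrix,
)
from .discretize import DiscretizationConfig, probe_medians, project_segments, symbolize
from .hmm import compose_paths, posterior, train_mle, viterbi
from .smoothing import rgep, sgep_matrix
from . import hmm as _hmm

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ContingencyTable") -> "ContingencyTable":
        return ContingencyTable(self.tp + other.tp, self.fp + other.fp,
                                self.tn + other.tn, self.fn + other.fn)


def contingency(pred: np.ndarray, truth: np.ndarray, label: str) -> ContingencyTable:
    """One-vs-rest 2x2 tally of predicted vs true labels for one target label."""
    pred = np.asarray(pred, dtype="<U1")
    truth = np.asarray(truth, dtype="<U1")
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    p = pred == label
    t = truth == label
    return ContingencyTable(tp=int((p & t).sum()), fp=int((p & ~t).sum()),
                            tn=int((~p & ~t).sum()), fn=int((~p & t).sum()))


def metrics(t: ContingencyTable) -> dict[str, float]:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy; NaN when
    a denominator is empty (undefined, excluded from averaging)."""
    sens = t.tp / (t.tp + t.fn) if t.tp + t.fn > 0 else math.nan
    spec = t.tn / (t.tn + t.fp) if t.tn + t.fp > 0 else math.nan
    acc = (t.tp + t.tn) / t.total if t.total > 0 else math.nan
    return {"sensitivity": sens, "specificity": spec, "accuracy": acc}


def frequency_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation between two per-cytoband frequency vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frequency vectors differ in length")
    if a.std() == 0 or b.std() == 0:
        return math.nan
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class LoocvConfig:
    disc: DiscretizationConfig = field(default_factory=DiscretizationConfig)
    pseudocount: float = 0.5
    decoder: str = "viterbi"          # viterbi | posterior
    posterior_cutoff: float = 0.5
    lod_cutoff: float = 2.0
    min_aberrant_training: int = 3
    exclude_chroms: tuple[str, ...] = ()


@dataclass
class LoocvResult:
    """Truth and per-method predictions across all held-out samples.

    ``predictions`` holds probe-level matrices for 'vcgh' (the configured
    decoder), 'rgep' and 'sgep'; ``posterior_tracks`` keeps the CNA
    marginals (probes x samples x 3, columns +/-/o) so calls at any
    posterior cutoff can be re-thresholded without re-running the folds.
    """

    truth: CnaMatrix
    predictions: dict[str, CnaMatrix]
    posterior_tracks: np.ndarray
    annotation: GenomeAnnotation
    warnings: list[tuple[str, str]]
    config: LoocvConfig

    @property
    def sample_ids(self) -> list[str]:
        return self.truth.sample_ids

    def calls_at_cutoff(self, cutoff: float) -> CnaMatrix:
        if not 0.5 <= cutoff <= 1:
            raise ValueError("posterior cutoff must lie in [0.5, 1]")
        m = self.posterior_tracks  # (probes, samples, 3); all-zero rows are
        out = np.full(m.shape[:2], NEUTRAL, dtype="<U1")  # undecoded chroms
        out[(m[..., 0] >= cutoff) & (m[..., 0] > m[..., 1])] = GAIN
        out[(m[..., 1] >= cutoff) & (m[..., 1] > m[..., 0])] = LOSS
        return CnaMatrix(out, self.annotation, self.sample_ids)

    def fold_metrics(self, method: str, label: str,
                     chrom: str | None = None) -> pd.DataFrame:
        """Per-held-out-sample sensitivity/specificity/accuracy."""
        pred = self.predictions[method]
        rows = []
        for j, sid in enumerate(self.sample_ids):
            if chrom is None:
                p, t = pred.values[:, j], self.truth.values[:, j]
            else:
                sl = self.annotation.chrom_slices[chrom]
                p, t = pred.values[sl, j], self.truth.values[sl, j]
            rows.append({"sample": sid,
                         **metrics(contingency(p, t, label))})
        return pd.DataFrame(rows).set_index("sample")

    def summary(self, methods: tuple[str, ...] = ("vcgh", "rgep", "sgep"),
                per_chrom: bool = False) -> pd.DataFrame:
        """Mean +/- sd over folds, genome-wide and optionally per chromosome."""
        rows = []
        chroms: list[str | None] = [None]
        if per_chrom:
            chroms += self.annotation.chroms
        for method in methods:
            for label in (GAIN, LOSS):
                for chrom in chroms:
                    fm = self.fold_metrics(method, label, chrom)
                    row = {"method": method, "label": label,
                           "chromosome": chrom or "genome"}
                    for m in ("sensitivity", "specificity", "accuracy"):
                        vals = fm[m].dropna()
                        row[f"{m}_mean"] = vals.mean() if len(vals) else math.nan
                        row[f"{m}_sd"] = vals.std(ddof=1) if len(vals) > 1 \
                            else math.nan
                    rows.append(row)
        return pd.DataFrame(rows)

    def pooled_metrics(self, method: str, label: str) -> dict[str, float]:
        """Metrics from probe x sample cells pooled across all folds."""
        return metrics(contingency(self.predictions[method].values,
                                   self.truth.values, label))


def _active_chroms(ann: GenomeAnnotation, exclude: tuple[str, ...]) -> list[str]:
    return [c for c in ann.chroms if c not in exclude]


def loocv(expr: ExpressionMatrix, truth_segments: SegmentSet,
          ann: GenomeAnnotation,
          cfg: LoocvConfig = LoocvConfig()) -> LoocvResult:
    """Leave-one-out cross-validation of vCGH against rGEP and sGEP."""
    samples = expr.sample_ids
    if len(samples) < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    if cfg.decoder not in ("viterbi", "posterior"):
        raise ValueError(f"unknown decoder {cfg.decoder!r}")
    chroms = _active_chroms(ann, cfg.exclude_chroms)
    truth = project_segments(truth_segments, ann, sample_ids=samples)

    n_probes, n_samples = expr.shape
    vit = np.full((n_probes, n_samples), NEUTRAL, dtype="<U1")
    tracks = np.zeros((n_probes, n_samples, 3))
    test_symbols = np.full((n_probes, n_samples), "M", dtype="<U1")
    warn: set[tuple[str, str]] = set()

    for j, held_out in enumerate(samples):
        train_ids = [s for s in samples if s != held_out]
        train_expr = expr.subset_samples(train_ids)
        medians = probe_medians(train_expr)
        train_sym = symbolize(train_expr, cfg.disc)
        held_sym = symbolize(expr.subset_samples([held_out]), cfg.disc,
                             medians=medians)
        test_symbols[:, j] = held_sym.values[:, 0]
        t_idx = [samples.index(s) for s in train_ids]
        for chrom in chroms:
            sl = ann.chrom_slices[chrom]
            paths = [compose_paths(train_sym.values[sl, k],
                                   truth.values[sl, samples.index(s)])
                     for k, s in enumerate(train_ids)]
            for label in (GAIN, LOSS):
                n_ab = sum((truth.values[sl][:, t_idx] == label).any(axis=0))
                if n_ab < cfg.min_aberrant_training:
                    warn.add((chrom, label))
            params = train_mle(paths, chrom=chrom, pseudocount=cfg.pseudocount)
            obs = held_sym.values[sl, 0]
            path, _ = viterbi(params, obs)
            vit[sl, j] = _hmm.decompose_path(path)[1]
            tracks[sl, j, :] = posterior(params, obs).marginals

    sym_mat = SymbolMatrix(test_symbols, ann, samples)
    result = LoocvResult(
        truth=truth,
        predictions={"rgep": rgep(sym_mat),
                     "sgep": sgep_matrix(sym_mat, ann, cfg.lod_cutoff)},
        posterior_tracks=tracks,
        annotation=ann,
        warnings=sorted(warn),
        config=cfg,
    )
    result.predictions["viterbi"] = CnaMatrix(vit, ann, samples)
    result.predictions["posterior"] = result.calls_at_cutoff(cfg.posterior_cutoff)
    result.predictions["vcgh"] = result.predictions[cfg.decoder]
    if warn:
        for chrom, label in sorted(warn):
            log.warning("chromosome %s label %s: fewer than %d aberrant "
                        "training samples", chrom, label,
                        cfg.min_aberrant_training)
    return result


def cytoband_frequencies(calls: CnaMatrix) -> pd.DataFrame:
    """Number of samples harboring a gain / loss on each cytoband."""
    ann = calls.annotation
    rows = []
    for (chrom, band), sl in ann.cytoband_slices.items():
        sub = calls.values[sl]
        rows.append({
            "chrom": chrom, "cytoband": band,
            "gain": int(((sub == GAIN).any(axis=0)).sum()),
            "loss": int(((sub == LOSS).any(axis=0)).sum()),
        })
    return pd.DataFrame(rows)
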