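"""Model/Results facade over the pipeline.

:class:`VCGH` is built from paired expression and CGH-segment data aligned
to a genome annotation; :meth:`VCGH.fit` estimates one 9-state HMM per
chromosome by supervised maximum likelihood and returns a
:class:`VCGHResults` carrying the fitted parameters, prediction methods
(Viterbi or posterior decoding, cytoband smoothing) and a text summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CnaMatrix, ExpressionMatrix, GenomeAnnotation, SegmentSet
from .discretize import DiscretizationConfig, probe_medians, project_segments, symbolize
from .hmm import (
    HmmParams, STATES, call_posterior, compose_paths, decompose_path,
    posterior, train_mle, viterbi,
)
from .smoothing import CytobandCall, call_cytobands


class VCGH:
    """Expression-to-copy-number predictor trained on a paired cohort.

    Parameters
    ----------
    expression
        Linear-scale intensities, probes x samples, aligned to *annotation*.
    segments
        Per-sample experimental CGH gain/loss segments (the training truth).
    annotation
        Probe coordinates and cytoband membership; defines chain order.
    disc
        Discretization thresholds (1.5-fold expression, 1.25/0.75 ratios).
    pseudocount
        Additive smoothing on transition and initial counts.
    exclude_chroms
        Chromosomes to leave out of training and prediction.
    """

    def __init__(self, expression: ExpressionMatrix, segments: SegmentSet,
                 annotation: GenomeAnnotation,
                 disc: DiscretizationConfig = DiscretizationConfig(),
                 pseudocount: float = 0.5,
                 exclude_chroms: tuple[str, ...] = ()):
        self.expression = expression
        self.segments = segments
        self.annotation = annotation
        self.disc = disc
        self.pseudocount = pseudocount
        self.exclude_chroms = tuple(exclude_chroms)

    @classmethod
    def from_files(cls, expression_path, segments_path, annotation_path,
                   **kwargs) -> "VCGH":
        from . import io
        ann = io.read_annotation(annotation_path)
        expr = io.read_expression(expression_path, ann)
        segs = io.read_segments(segments_path)
        return cls(expr, segs, ann, **kwargs)

    @property
    def chroms(self) -> list[str]:
        return [c for c in self.annotation.chroms
                if c not in self.exclude_chroms]

    def fit(self) -> "VCGHResults":
        ann = self.annotation
        samples = self.expression.sample_ids
        medians = probe_medians(self.expression)
        symbols = symbolize(self.expression, self.disc)
        truth = project_segments(self.segments, ann, sample_ids=samples)
        params: dict[str, HmmParams] = {}
        for chrom in self.chroms:
            sl = ann.chrom_slices[chrom]
            paths = [compose_paths(symbols.values[sl, j], truth.values[sl, j])
                     for j in range(len(samples))]
            params[chrom] = train_mle(paths, chrom=chrom,
                                      pseudocount=self.pseudocount)
        return VCGHResults(model=self, params=params,
                           training_medians=medians, n_train=len(samples))


@dataclass
class VCGHResults:
    """Fitted per-chromosome HMM parameters and prediction methods."""

    model: VCGH | None
    params: dict[str, HmmParams]
    training_medians: np.ndarray | None = None
    n_train: int = 0
    disc: DiscretizationConfig = field(default_factory=DiscretizationConfig)

    def __post_init__(self):
        if self.model is not None:
            self.disc = self.model.disc

    def _require_chrom(self, chrom: str) -> HmmParams:
        if chrom not in self.params:
            raise KeyError(
                f"model has no parameters for chromosome {chrom!r}")
        return self.params[chrom]

    def predict(self, expression: ExpressionMatrix,
                decoder: str = "viterbi",
                posterior_cutoff: float = 0.5,
                use_training_medians: bool = True) -> CnaMatrix:
        """Decode CNA labels for new samples from expression alone."""
        if decoder not in ("viterbi", "posterior"):
            raise ValueError(f"unknown decoder {decoder!r}")
        ann = expression.annotation
        medians = self.training_medians if (use_training_medians and
                                            self.training_medians is not None) \
            else None
        symbols = symbolize(expression, self.disc, medians=medians)
        out = np.full(expression.shape, "o", dtype="<U1")
        for chrom in ann.chroms:
            if self.model is not None and chrom in self.model.exclude_chroms:
                continue
            p = self._require_chrom(chrom)
            sl = ann.chrom_slices[chrom]
            for j in range(len(expression.sample_ids)):
                obs = symbols.values[sl, j]
                if decoder == "viterbi":
                    path, _ = viterbi(p, obs)
                    out[sl, j] = decompose_path(path)[1]
                else:
                    out[sl, j] = call_posterior(posterior(p, obs),
                                                posterior_cutoff)
        return CnaMatrix(out, ann, expression.sample_ids)

    def predict_cytobands(self, expression: ExpressionMatrix,
                          lod_cutoff: float = 2.0,
                          **kwargs) -> dict[str, list[CytobandCall]]:
        """Probe-level prediction followed by cytoband LOD smoothing."""
        calls = self.predict(expression, **kwargs)
        ann = expression.annotation
        return {sid: call_cytobands(calls.values[:, j], ann, lod_cutoff)
                for j, sid in enumerate(calls.sample_ids)}

    def summary(self) -> str:
        lines = ["vCGH fitted model",
                 f"  chromosomes: {len(self.params)}",
                 f"  training samples: {self.n_train}",
                 f"  states: {', '.join(STATES)}", ""]
        rows = []
        for chrom, p in self.params.items():
            stay = np.diag(p.transition)
            rows.append({
                "chromosome": chrom,
                "pi(gain)": p.initial[:3].sum(),
                "pi(loss)": p.initial[3:6].sum(),
                "pi(normal)": p.initial[6:].sum(),
                "mean self-transition": stay.mean(),
            })
        table = pd.DataFrame(rows).to_string(index=False,
                                             float_format="%.4f")
        return "\n".join(lines) + table
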