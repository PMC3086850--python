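"""Readers and writers for every file the tool touches.

All tabular formats are tab-separated text; lines starting with ``#`` are
comments.  Coordinates are 0-based half-open, as in BED.
"""

from __future__ import annotations

import json
import logging

import numpy as np
import pandas as pd

from .core import (
    GAIN, LOSS, NEUTRAL, CnaMatrix, GenomeAnnotation, ExpressionMatrix,
    Segment, SegmentSet,
)

log = logging.getLogger(__name__)

_READ_KW = dict(sep="\t", comment="#")


def read_annotation(path) -> GenomeAnnotation:
    """Read a probe annotation table: probe_id, chrom, start, end, cytoband."""
    df = pd.read_csv(path, **_READ_KW, dtype={"probe_id": str, "chrom": str,
                                              "cytoband": str})
    df.columns = [c.strip() for c in df.columns]
    return GenomeAnnotation(df)


def read_expression(path, annotation: GenomeAnnotation,
                    scale: str = "linear") -> ExpressionMatrix:
    """Read an expression matrix (header of sample ids, first column probe ids).

    Probes absent from *annotation* are dropped (count logged); probes in the
    annotation must all be present.
    """
    df = pd.read_csv(path, **_READ_KW, index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate probe id {dup!r} in expression matrix")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValueError(
                f"non-numeric expression value {bad.iloc[0]!r} at probe "
                f"{bad.index[0]!r}, sample {col!r}"
            )
    if df.empty:
        raise ValueError("empty expression matrix")
    known = set(annotation.probe_ids)
    drop = [p for p in df.index if p not in known]
    if drop:
        log.info("dropping %d probe(s) absent from annotation", len(drop))
        df = df.drop(index=drop)
    missing = known - set(df.index)
    if missing:
        raise ValueError(
            f"{len(missing)} annotation probe(s) missing from expression "
            f"matrix, e.g. {sorted(missing)[0]!r}"
        )
    df = df.loc[annotation.probe_ids]
    return ExpressionMatrix(df.to_numpy(float), annotation,
                            [str(c) for c in df.columns], scale=scale)


_LABEL_TOKENS = {"+": GAIN, "-": LOSS, "gain": GAIN, "loss": LOSS}


def read_segments(path, gain_ratio: float = 1.25,
                  loss_ratio: float = 0.75) -> SegmentSet:
    """Read BED-like per-sample CNA segments: sample, chrom, start, end, label.

    The label column holds ``+``/``-`` (or ``gain``/``loss``) or a numeric
    tumor/normal ratio, thresholded at *gain_ratio*/*loss_ratio*; ratio rows
    falling in the normal band are dropped.
    """
    segs: dict[str, list[Segment]] = {}
    df = pd.read_csv(path, **_READ_KW, header=None,
                     names=["sample", "chrom", "start", "end", "label"],
                     dtype={"sample": str, "chrom": str, "label": str})
    for row in df.itertuples(index=False):
        token = str(row.label).strip()
        if token.lower() in _LABEL_TOKENS:
            label = _LABEL_TOKENS[token.lower()]
        else:
            try:
                ratio = float(token)
            except ValueError:
                raise ValueError(f"unknown segment label {token!r}") from None
            if ratio <= 0:
                raise ValueError(f"non-positive segment ratio {ratio}")
            if ratio > gain_ratio:
                label = GAIN
            elif ratio < loss_ratio:
                label = LOSS
            else:
                continue
        segs.setdefault(row.sample, []).append(
            Segment(row.chrom, int(row.start), int(row.end), label))
    return SegmentSet(segs)


def write_segments(segset: SegmentSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("# sample\tchrom\tstart\tend\tlabel\n")
        for sample, segs in segset.segments.items():
            for s in segs:
                fh.write(f"{sample}\t{s.chrom}\t{s.start}\t{s.end}\t{s.label}\n")


def write_annotation(ann: GenomeAnnotation, path) -> None:
    ann.table.to_csv(path, sep="\t", index=False)


def write_expression(expr: ExpressionMatrix, path) -> None:
    pd.DataFrame(expr.values, index=expr.probe_ids,
                 columns=expr.sample_ids).to_csv(path, sep="\t",
                                                 index_label="probe_id")


def write_calls(calls: CnaMatrix, path) -> None:
    """Write per-probe calls as TSV rows (probe, sample, label)."""
    with open(path, "w") as fh:
        fh.write("# probe\tsample\tlabel\n")
        for j, sample in enumerate(calls.sample_ids):
            for i, probe in enumerate(calls.probe_ids):
                fh.write(f"{probe}\t{sample}\t{calls.values[i, j]}\n")


def read_calls(path, annotation: GenomeAnnotation) -> CnaMatrix:
    df = pd.read_csv(path, **_READ_KW, header=None,
                     names=["probe", "sample", "label"],
                     dtype=str)
    samples = list(dict.fromkeys(df["sample"]))
    mat = np.full((annotation.n_probes, len(samples)), NEUTRAL, dtype="<U1")
    sidx = {s: j for j, s in enumerate(samples)}
    for row in df.itertuples(index=False):
        mat[annotation.probe_index(row.probe), sidx[row.sample]] = row.label
    return CnaMatrix(mat, annotation, samples)


def calls_to_segments(calls: CnaMatrix) -> SegmentSet:
    """Run-length merge adjacent same-label probes into genomic segments."""
    ann = calls.annotation
    starts = ann.table["start"].to_numpy()
    ends = ann.table["end"].to_numpy()
    segs: dict[str, list[Segment]] = {s: [] for s in calls.sample_ids}
    for j, sample in enumerate(calls.sample_ids):
        col = calls.values[:, j]
        for chrom, sl in ann.chrom_slices.items():
            labels = col[sl]
            i = 0
            n = sl.stop - sl.start
            while i < n:
                lab = labels[i]
                k = i
                while k + 1 < n and labels[k + 1] == lab:
                    k += 1
                if lab != NEUTRAL:
                    segs[sample].append(Segment(
                        chrom, int(starts[sl.start + i]),
                        int(ends[sl.start + k]), lab))
                i = k + 1
    return SegmentSet(segs)


def write_call_segments(calls: CnaMatrix, path) -> None:
    """Write predicted per-sample segments as BED (chrom start end sample label)."""
    segset = calls_to_segments(calls)
    with open(path, "w") as fh:
        for sample, segs in segset.segments.items():
            for s in segs:
                fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{sample}\t{s.label}\n")


def write_cytoband_calls(rows: list[dict], path) -> None:
    """Cytoband call table: sample, cytoband, n_plus, n_minus, n_o, lod, call."""
    cols = ["sample", "chrom", "cytoband", "n_plus", "n_minus", "n_o", "lod", "call"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# --- model serialization -------------------------------------------------

def write_model(params_by_chrom: dict, path, meta: dict | None = None) -> None:
    """Serialize trained per-chromosome HMM parameters as self-describing JSON."""
    from .hmm import STATES, ALPHABET
    doc = {
        "format": "vcgh-model",
        "version": 1,
        "states": list(STATES),
        "alphabet": list(ALPHABET),
        "meta": meta or {},
        "chromosomes": {
            chrom: {
                "initial": p.initial.tolist(),
                "transition": p.transition.tolist(),
            }
            for chrom, p in params_by_chrom.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_model(path) -> dict:
    from .hmm import HmmParams, STATES, ALPHABET
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "vcgh-model":
        raise ValueError(f"{path}: not a vcgh model file")
    if tuple(doc["states"]) != STATES or tuple(doc["alphabet"]) != ALPHABET:
        raise ValueError(f"{path}: state space does not match this version")
    return {
        chrom: HmmParams(chrom=chrom,
                         initial=np.array(d["initial"]),
                         transition=np.array(d["transition"]))
        for chrom, d in doc["chromosomes"].items()
    }
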