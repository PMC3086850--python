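"""Permutation test linking a recurrent predicted abnormality to expression.

For a region called as a recurrent gain (or loss), samples split into
aberrant and wild-type groups.  Each region probe gets a one-sided
two-sample t-test p-value in the dosage direction (gain: aberrant >
wild-type; loss: aberrant < wild-type); the region statistic is the sum of
ln(p) over probes — small when expression moves coherently with the
abnormality.  Group labels are permuted (group sizes preserved) to build
the null; the empirical p-value uses the add-one correction, so it is
never exactly zero.  Samples carrying both a gain and a loss in the
region are excluded from both groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import ExpressionMatrix, GenomeAnnotation

log = logging.getLogger(__name__)


@dataclass
class RegionGrouping:
    """Region membership and sample partition for one association test."""

    chrom: str
    start: int
    end: int
    direction: str                    # "gain" or "loss"
    aberrant: list[str] = field(default_factory=list)
    wildtype: list[str] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.direction not in ("gain", "loss"):
            raise ValueError(f"direction must be gain or loss, "
                             f"got {self.direction!r}")
        groups = [set(self.aberrant), set(self.wildtype), set(self.excluded)]
        if sum(len(g) for g in groups) != len(set().union(*groups)):
            raise ValueError("aberrant/wildtype/excluded groups overlap")


@dataclass
class AssociationResult:
    observed_statistic: float
    permuted_statistics: np.ndarray
    empirical_p: float
    n_probes: int
    n_aberrant: int
    n_wildtype: int


def _one_sided_p(data: np.ndarray, is_aberrant: np.ndarray, sign: float,
                 equal_var: bool) -> np.ndarray:
    """Vectorized per-probe one-sided two-sample t-test p-values.

    sign +1 tests aberrant > wildtype, -1 tests aberrant < wildtype.
    Probes with zero variance in both groups get p = 1.
    """
    a = data[:, is_aberrant]
    w = data[:, ~is_aberrant]
    na, nw = a.shape[1], w.shape[1]
    ma, mw = a.mean(axis=1), w.mean(axis=1)
    va, vw = a.var(axis=1, ddof=1), w.var(axis=1, ddof=1)
    if equal_var:
        sp2 = ((na - 1) * va + (nw - 1) * vw) / (na + nw - 2)
        se2 = sp2 * (1 / na + 1 / nw)
        df = np.full(len(data), na + nw - 2, dtype=float)
    else:  # Welch
        se2 = va / na + vw / nw
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2 ** 2 / ((va / na) ** 2 / (na - 1)
                             + (vw / nw) ** 2 / (nw - 1))
    p = np.ones(len(data))
    ok = se2 > 0
    t = sign * (ma[ok] - mw[ok]) / np.sqrt(se2[ok])
    p[ok] = stats.t.sf(t, df[ok])
    if (~ok).any():
        log.info("%d zero-variance probe(s); p set to 1", int((~ok).sum()))
    return p


def region_test(expr: ExpressionMatrix, grouping: RegionGrouping,
                ann: GenomeAnnotation, n_perm: int = 1000,
                seed: int | np.random.Generator = 0,
                equal_var: bool = False) -> AssociationResult:
    """Permutation test of coordinated expression change in a region."""
    if len(grouping.aberrant) < 2 or len(grouping.wildtype) < 2:
        raise ValueError("need at least 2 samples in each of "
                         "aberrant and wildtype groups")
    if grouping.chrom not in ann.chrom_slices:
        raise ValueError(f"chromosome {grouping.chrom!r} not in annotation")
    sl = ann.chrom_slices[grouping.chrom]
    mids = ann.midpoints()[sl]
    in_region = (mids >= grouping.start) & (mids < grouping.end)
    if not in_region.any():
        raise ValueError("no probes in region")
    probe_rows = np.arange(sl.start, sl.stop)[in_region]

    used = grouping.aberrant + grouping.wildtype
    cols = [expr.sample_index(s) for s in used]
    data = expr.values[np.ix_(probe_rows, cols)]
    na = len(grouping.aberrant)
    is_ab = np.zeros(len(used), dtype=bool)
    is_ab[:na] = True
    sign = 1.0 if grouping.direction == "gain" else -1.0

    observed = float(np.log(_one_sided_p(data, is_ab, sign, equal_var)).sum())
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    perm_stats = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(len(used))
        perm_mask = np.zeros(len(used), dtype=bool)
        perm_mask[perm[:na]] = True
        perm_stats[i] = np.log(
            _one_sided_p(data, perm_mask, sign, equal_var)).sum()
    empirical_p = (1 + int((perm_stats <= observed).sum())) / (n_perm + 1)
    return AssociationResult(
        observed_statistic=observed,
        permuted_statistics=perm_stats,
        empirical_p=empirical_p,
        n_probes=len(probe_rows),
        n_aberrant=na,
        n_wildtype=len(grouping.wildtype),
    )


def grouping_from_calls(calls, chrom: str, start: int, end: int,
                        direction: str) -> RegionGrouping:
    """Partition samples by their calls in a region: samples with only the
    tested label are aberrant, with neither label wild-type, with both
    excluded."""
    ann = calls.annotation
    sl = ann.chrom_slices[chrom]
    mids = ann.midpoints()[sl]
    rows = np.arange(sl.start, sl.stop)[(mids >= start) & (mids < end)]
    target = "+" if direction == "gain" else "-"
    other = "-" if direction == "gain" else "+"
    aberrant, wildtype, excluded = [], [], []
    for j, sid in enumerate(calls.sample_ids):
        col = calls.values[rows, j]
        has_t, has_o = (col == target).any(), (col == other).any()
        if has_t and has_o:
            excluded.append(sid)
        elif has_t:
            aberrant.append(sid)
        else:
            wildtype.append(sid)
    return RegionGrouping(chrom, start, end, direction,
                          aberrant=aberrant, wildtype=wildtype,
                          excluded=excluded)
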