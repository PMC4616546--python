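"""Genome-wide screen for subtype-specific genes.

The screen works on reference-normalized expression and selects genes
satisfying two conditions simultaneously:

1. median expression in the *target* subtype strictly above
   ``median_min`` (default 8), and
2. the ``percentile``-th (default 95th) percentile of expression strictly
   below ``background_q_max`` (default 0.15) in *every* background
   subtype separately.

Condition 1 demands that the gene is robustly expressed in most target
samples; condition 2 that it is essentially silent even in the upper tail
of each background subtype, which is what makes an immunostain against
the product diagnostically clean.  The filter is deterministic — no
fold-change test, no multiple-testing machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import NormalizedMatrix, SampleAnnotation
from ._format import percent

log = logging.getLogger(__name__)

__all__ = [
    "ScreenCriteria",
    "SubtypeSummary",
    "MarkerHit",
    "percentile",
    "summarize_by_subtype",
    "apply_screen",
    "condition_counts",
]

#: supported percentile conventions
_PCT_METHODS = {"linear": "linear", "nearest-rank": "inverted_cdf"}


@dataclass(frozen=True)
class ScreenCriteria:
    """Thresholds of the two-condition filter.

    Defaults are the published operating point for the chromophobe RCC
    screen on TBP-normalized expression: target median > 8, background
    95th percentile < 0.15.  Both thresholds are strict inequalities.
    """

    target_subtype: str
    median_min: float = 8.0
    background_q_max: float = 0.15
    percentile: float = 95.0
    reference_gene: str = "TBP"

    def __post_init__(self) -> None:
        if self.median_min <= 0:
            raise ValueError("median_min must be > 0")
        if self.background_q_max < 0:
            raise ValueError("background_q_max must be >= 0")
        if not (0 < self.percentile <= 100):
            raise ValueError("percentile must be in (0, 100]")


@dataclass(frozen=True)
class SubtypeSummary:
    """Per-gene, per-subtype medians and q-th percentiles."""

    medians: pd.DataFrame      # genes x subtypes
    percentiles: pd.DataFrame  # genes x subtypes
    q: float
    n_samples: dict[str, int]

    @property
    def subtypes(self) -> list[str]:
        return list(self.medians.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.medians.index)


@dataclass(frozen=True)
class MarkerHit:
    """One gene's screen outcome: summaries plus per-condition flags."""

    gene_id: str
    target_median: float
    background_percentiles: dict[str, float]
    cond1: bool
    cond2: dict[str, bool]

    @property
    def hit(self) -> bool:
        return self.cond1 and all(self.cond2.values())


def percentile(values, q: float, method: str = "linear") -> float:
    """q-th percentile of a sample by linear interpolation of order statistics.

    With sorted values x(1..n), the linear convention evaluates position
    p = 1 + (q/100)(n-1) and interpolates between the bracketing order
    statistics.  ``method="nearest-rank"`` instead returns the smallest
    order statistic whose rank is >= q*n/100 (inverted CDF).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("percentile of an empty sample is undefined")
    if not np.isfinite(arr).all():
        raise ValueError("percentile input contains non-finite values")
    if not (0 < q <= 100):
        raise ValueError("q must be in (0, 100]")
    try:
        np_method = _PCT_METHODS[method]
    except KeyError:
        raise ValueError(
            f"unknown percentile method {method!r}; use one of {sorted(_PCT_METHODS)}"
        ) from None
    return float(np.percentile(arr, q, method=np_method))


def summarize_by_subtype(
    nm: NormalizedMatrix,
    ann: SampleAnnotation,
    q: float = 95.0,
    min_samples: int = 3,
    method: str = "linear",
) -> SubtypeSummary:
    """Median and q-th percentile of each gene within each subtype.

    Only samples present in both the matrix and the annotation enter the
    summaries; unannotated matrix samples are excluded with a logged
    count.  A subtype with fewer than ``min_samples`` annotated samples
    in the matrix is a hard error — medians over tiny groups would be
    dominated by single cases.
    """
    cols = [s for s in nm.sample_ids if s in ann.labels.index]
    n_skipped = len(nm.sample_ids) - len(cols)
    if n_skipped:
        log.info("excluding %d sample(s) absent from the annotation", n_skipped)
    if not cols:
        raise ValueError("no overlap between matrix samples and annotation")
    sub = nm.values[cols]
    groups = ann.labels.loc[cols]

    medians: dict[str, np.ndarray] = {}
    percentiles: dict[str, np.ndarray] = {}
    n_samples: dict[str, int] = {}
    for subtype in ann.subtypes:
        members = [c for c in cols if groups[c] == subtype]
        if len(members) < min_samples:
            raise ValueError(
                f"subtype {subtype!r} has only {len(members)} sample(s) in the matrix; "
                f"need at least {min_samples}"
            )
        block = sub[members].to_numpy()
        medians[subtype] = np.median(block, axis=1)
        percentiles[subtype] = np.percentile(block, q, axis=1, method=_PCT_METHODS[method])
        n_samples[subtype] = len(members)

    idx = nm.values.index
    return SubtypeSummary(
        medians=pd.DataFrame(medians, index=idx),
        percentiles=pd.DataFrame(percentiles, index=idx),
        q=q,
        n_samples=n_samples,
    )


def _split_subtypes(s: SubtypeSummary, c: ScreenCriteria) -> list[str]:
    if c.target_subtype not in s.subtypes:
        raise ValueError(f"target subtype {c.target_subtype!r} absent from summary")
    backgrounds = [b for b in s.subtypes if b != c.target_subtype]
    if not backgrounds:
        raise ValueError("screen needs at least one background subtype")
    return backgrounds


def apply_screen(s: SubtypeSummary, c: ScreenCriteria) -> list[MarkerHit]:
    """Evaluate both conditions for every gene.

    Returns one :class:`MarkerHit` per gene with full flag vectors
    (condition 2 is evaluated separately for every background subtype),
    sorted by target median descending, ties broken by gene id.
    """
    backgrounds = _split_subtypes(s, c)
    med = s.medians[c.target_subtype]
    hits = []
    for gene in s.gene_ids:
        bg_pct = {b: float(s.percentiles.at[gene, b]) for b in backgrounds}
        hits.append(
            MarkerHit(
                gene_id=gene,
                target_median=float(med[gene]),
                background_percentiles=bg_pct,
                cond1=bool(med[gene] > c.median_min),
                cond2={b: bool(v < c.background_q_max) for b, v in bg_pct.items()},
            )
        )
    hits.sort(key=lambda h: (-h.target_median, h.gene_id))
    n_hits = sum(h.hit for h in hits)
    log.info("screen: %d / %d genes pass both conditions", n_hits, len(hits))
    return hits


def selected_genes(hits: list[MarkerHit]) -> list[str]:
    """Gene ids passing both conditions, in report order."""
    return [h.gene_id for h in hits if h.hit]


def condition_counts(s: SubtypeSummary, c: ScreenCriteria) -> dict:
    """Counts and display percentages of genes passing each condition.

    Fractions are reported as percentages half-up rounded to one decimal
    (e.g. 3333 of 20531 genes -> 16.2).
    """
    backgrounds = _split_subtypes(s, c)
    total = len(s.gene_ids)
    n1 = int((s.medians[c.target_subtype] > c.median_min).sum())
    out = {
        "total_genes": total,
        "condition1": {"count": n1, "percent": percent(n1, total)},
        "condition2": {},
    }
    for b in backgrounds:
        n2 = int((s.percentiles[b] < c.background_q_max).sum())
        out["condition2"][b] = {"count": n2, "percent": percent(n2, total)}
    return out


def hits_frame(hits: list[MarkerHit], q: float = 95.0) -> pd.DataFrame:
    """Flatten screen results to a table (one row per gene, flags included)."""
    qtag = f"q{q:g}"
    rows = []
    for h in hits:
        row: dict = {"gene_id": h.gene_id, "target_median": h.target_median}
        for b, v in sorted(h.background_percentiles.items()):
            row[f"{qtag}_{b}"] = v
        row["cond1"] = h.cond1
        for b, v in sorted(h.cond2.items()):
            row[f"cond2_{b}"] = v
        row["hit"] = h.hit
        rows.append(row)
    return pd.DataFrame(rows)
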