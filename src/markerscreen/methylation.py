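"""Methylation-expression association across tumor subtypes.

For each CpG probe the analysis computes, on the samples shared by the
beta-value table, the normalized expression matrix and the annotation:

* per-subtype median beta values and the *hypomethylation gap*
  ``delta_median`` — the smallest excess of any background subtype's
  median beta over the target subtype's median.  A probe is flagged
  hypomethylated in the target when that gap strictly exceeds a
  threshold (default 0.25);
* a Kruskal-Wallis test of beta across the subtypes (tie-corrected,
  chi-square approximation); and
* the Spearman rank correlation of beta with the linked gene's
  normalized expression, pooled over all shared samples and also within
  each subtype.

Beta values are the methylated fraction at a CpG site, in [0, 1]; an
inverse beta-expression correlation at promoter CpGs is the classical
signature of methylation-driven silencing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import MethylationTable, NormalizedMatrix, SampleAnnotation

log = logging.getLogger(__name__)

__all__ = ["CpGAssociation", "kruskal_wallis", "spearman", "associate", "association_frame"]


@dataclass(frozen=True)
class CpGAssociation:
    """Association summary for one CpG probe."""

    probe_id: str
    gene_id: str
    subtype_medians: dict[str, float]
    delta_median: float
    hypo_flag: bool
    kw_H: float
    kw_p: float
    rho: float            # pooled Spearman rho (beta vs normalized expression)
    rho_p: float
    rho_by_subtype: dict[str, float]
    n_samples: int


def kruskal_wallis(
    groups: list,
    exact: bool = False,
    n_resamples: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and p across >=2 groups.

    The default p-value uses the chi-square approximation with k-1
    degrees of freedom.  ``exact=True`` computes a permutation p-value
    instead (exhaustive when feasible, otherwise ``n_resamples`` random
    group relabelings), intended for small groups (<= ~10 per group)
    where the chi-square approximation is rough.

    If every pooled observation is identical the statistic degenerates
    (the tie correction divides by zero); by convention H = 0, p = 1,
    with a logged warning.
    """
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, a in enumerate(arrays):
        if a.size == 0:
            raise ValueError(f"group {i} is empty")
        if not np.isfinite(a).all():
            raise ValueError(f"group {i} contains non-finite values")
    pooled = np.concatenate(arrays)
    if pooled.size < 3:
        raise ValueError("kruskal_wallis needs at least 3 observations in total")
    if np.all(pooled == pooled[0]):
        log.warning("kruskal_wallis: all observations identical; returning H=0, p=1")
        return 0.0, 1.0
    if not exact:
        res = stats.kruskal(*arrays)
        return float(res.statistic), float(res.pvalue)

    def statistic(*samples):
        return stats.kruskal(*samples).statistic

    res = stats.permutation_test(
        arrays,
        statistic,
        permutation_type="independent",
        alternative="greater",
        n_resamples=n_resamples,
        rng=np.random.default_rng(seed),
    )
    return float(res.statistic), float(res.pvalue)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with mid-rank tie handling.

    Equals the Pearson correlation of mid-ranks; p-value from the
    t-distribution approximation.  A constant input vector leaves rho
    undefined: returns (nan, nan) with a logged warning.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("spearman needs two equal-length 1-D vectors")
    if xa.size < 4:
        raise ValueError("spearman needs at least 4 paired observations")
    if not (np.isfinite(xa).all() and np.isfinite(ya).all()):
        raise ValueError("spearman input contains non-finite values")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        log.warning("spearman: constant input vector; rho undefined")
        return math.nan, math.nan
    rho, p = stats.spearmanr(xa, ya)
    return float(rho), float(p)


def associate(
    meth: MethylationTable,
    nm: NormalizedMatrix,
    ann: SampleAnnotation,
    probe_gene_map: dict[str, str] | pd.DataFrame,
    target_subtype: str,
    delta_threshold: float = 0.25,
) -> list[CpGAssociation]:
    """Per-probe subtype comparison and beta-expression correlation.

    ``probe_gene_map`` links each probe to the gene whose expression it
    is correlated with (two-column frame ``probe_id,gene_id`` or a
    dict).  All statistics are computed on the intersection of sample
    ids across the three inputs; missing beta values are excluded
    pairwise.  ``hypo_flag`` is true iff every background subtype's
    median beta exceeds the target's by strictly more than
    ``delta_threshold``.
    """
    if isinstance(probe_gene_map, pd.DataFrame):
        probe_gene_map = dict(
            zip(probe_gene_map.iloc[:, 0].astype(str), probe_gene_map.iloc[:, 1].astype(str))
        )

    shared = [
        s for s in meth.sample_ids
        if s in set(nm.sample_ids) and s in set(ann.labels.index)
    ]
    if not shared:
        raise ValueError("no samples shared between methylation, expression and annotation")
    log.info("methylation association on %d shared samples", len(shared))

    subtypes = ann.subtypes
    if target_subtype not in subtypes:
        raise ValueError(f"target subtype {target_subtype!r} absent from annotation")
    backgrounds = [s for s in subtypes if s != target_subtype]
    labels = ann.labels.loc[shared]

    out: list[CpGAssociation] = []
    for probe in meth.probe_ids:
        if probe not in probe_gene_map:
            raise ValueError(f"probe {probe!r} missing from the probe-gene map")
        gene = probe_gene_map[probe]
        if gene not in nm.values.index:
            raise ValueError(f"probe {probe!r} maps to gene {gene!r} absent from expression")

        beta = meth.beta.loc[probe, shared]
        expr = nm.values.loc[gene, shared]

        medians = {
            s: float(beta[labels == s].median()) for s in subtypes
        }
        delta = min(medians[b] - medians[target_subtype] for b in backgrounds)
        groups = [beta[labels == s].dropna().to_numpy() for s in subtypes]
        kw_H, kw_p = kruskal_wallis(groups)

        ok = beta.notna().to_numpy()
        rho, rho_p = spearman(beta[ok].to_numpy(), expr[ok].to_numpy())
        rho_by = {}
        for s in subtypes:
            mask = ((labels == s).to_numpy()) & ok
            if mask.sum() >= 4:
                r, _ = spearman(beta[mask].to_numpy(), expr[mask].to_numpy())
            else:
                r = math.nan
            rho_by[s] = r

        out.append(
            CpGAssociation(
                probe_id=probe,
                gene_id=gene,
                subtype_medians=medians,
                delta_median=float(delta),
                hypo_flag=bool(delta > delta_threshold),
                kw_H=kw_H,
                kw_p=kw_p,
                rho=rho,
                rho_p=rho_p,
                rho_by_subtype=rho_by,
                n_samples=int(ok.sum()),
            )
        )
    return out


def association_frame(assocs: list[CpGAssociation]) -> pd.DataFrame:
    """Flatten association records to a table (one row per probe)."""
    rows = []
    for a in assocs:
        row: dict = {"probe_id": a.probe_id, "gene_id": a.gene_id}
        for s, m in sorted(a.subtype_medians.items()):
            row[f"median_beta_{s}"] = m
        row.update(
            delta_median=a.delta_median,
            hypo_flag=a.hypo_flag,
            kw_H=a.kw_H,
            kw_p=a.kw_p,
            rho=a.rho,
            rho_p=a.rho_p,
            n_samples=a.n_samples,
        )
        for s, r in sorted(a.rho_by_subtype.items()):
            row[f"rho_{s}"] = r
        rows.append(row)
    return pd.DataFrame(rows)
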