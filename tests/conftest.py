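"""Shared fixtures and independent brute-force oracles.

The oracles reimplement each statistic from its definition (sort-and-
interpolate percentiles, mid-rank Spearman, tie-corrected Kruskal-Wallis,
triple-loop screen) without touching the package's code paths, so tests
compare two independent routes to the same number.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import markerscreen as ms

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")


# ---------------------------------------------------------------- oracles

def brute_percentile(values, q):
    """Linear interpolation between closest order statistics, by hand."""
    x = sorted(float(v) for v in values)
    n = len(x)
    if n == 1:
        return x[0]
    p = 1.0 + (q / 100.0) * (n - 1)
    lo = int(math.floor(p))
    frac = p - lo
    if lo >= n:
        return x[-1]
    return x[lo - 1] + frac * (x[lo] - x[lo - 1])


def brute_midranks(values):
    """Average ranks (1-based) with ties sharing the mean of their positions."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def brute_spearman(x, y):
    """Pearson correlation of mid-ranks."""
    rx = np.array(brute_midranks(list(x)))
    ry = np.array(brute_midranks(list(y)))
    rx -= rx.mean()
    ry -= ry.mean()
    return float(np.dot(rx, ry) / math.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))


def brute_kruskal_h(groups):
    """Tie-corrected Kruskal-Wallis H from the rank definition."""
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    ranks = brute_midranks(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        start += len(g)
        h += len(g) * (sum(r) / len(g) - (n + 1) / 2.0) ** 2
    h *= 12.0 / (n * (n + 1))
    # tie correction
    counts: dict[float, int] = {}
    for v in pooled:
        counts[v] = counts.get(v, 0) + 1
    tie = sum(t**3 - t for t in counts.values())
    return h / (1.0 - tie / (n**3 - n))


def brute_screen(medians: pd.DataFrame, percentiles: pd.DataFrame, target: str,
                 median_min: float, q_max: float) -> set[str]:
    """Triple-loop reimplementation of the two-condition filter."""
    hits = set()
    backgrounds = [c for c in medians.columns if c != target]
    for gene in medians.index:
        if not medians.at[gene, target] > median_min:
            continue
        ok = True
        for b in backgrounds:
            if not percentiles.at[gene, b] < q_max:
                ok = False
        if ok:
            hits.add(gene)
    return hits


# --------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def small_cohort():
    """Tiny deterministic normalized cohort: 4 genes x 9 samples, 3 subtypes."""
    samples = [f"s{i}" for i in range(9)]
    labels = pd.Series(["A"] * 3 + ["B"] * 3 + ["C"] * 3, index=samples)
    values = pd.DataFrame(
        {
            "TBP":  [1.0] * 9,
            "HOT":  [10.0, 12.0, 14.0, 0.01, 0.02, 0.03, 0.0, 0.01, 0.02],
            "FLAT": [1.0] * 9,
            "HIGH": [9.0] * 9,
        }
    ).T
    values.columns = samples
    nm = ms.NormalizedMatrix(values, reference_gene="TBP")
    return nm, ms.SampleAnnotation(labels)


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic cohort shared by read-only tests."""
    cfg = ms.SimulationConfig(seed=7)
    expr, ann, truth = ms.simulate_expression(cfg)
    return cfg, expr, ann, truth


@pytest.fixture()
def expr_tsv(tmp_path):
    """A small on-disk expression TSV."""
    p = tmp_path / "expr.tsv"
    p.write_text(
        "gene_id\ts1\ts2\n"
        "TBP\t2.0\t4.0\n"
        "A\t10.0\t8.0\n"
        "B\t0.0\t1.0\n"
    )
    return p
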