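"""Synthetic cohorts with planted ground truth.

The generator emulates the statistical structure the pipeline exploits:

* **Expression** — background genes follow a log-normal with a point
  mass at zero (dropout), so their within-subtype 95th percentiles sit
  far above the screen's background ceiling; planted marker genes are
  log-normal around a high median in their *hot* subtype and uniformly
  tiny (below a stated ceiling) everywhere else.  Values are generated
  on the reference-normalized scale and multiplied back by a strictly
  positive per-sample reference-gene value, so normalization recovers
  the designed matrix exactly.
* **Methylation** — for each planted marker, coupled CpG probes follow
  ``beta = clip(baseline - shift * z, 0, 1) + noise`` where ``z`` is the
  standardized log1p normalized expression of the marker: hot-subtype
  samples are hypomethylated and beta is inversely, monotonically
  coupled to expression.  Null probes are independent of expression.
  About 1% of entries are missing.
* **IHC** — one record per case x marker, grades drawn from configured
  per-tumor-type category distributions; with ``ihc_exact_counts`` the
  category counts are apportioned exactly (largest remainder), which
  reproduces a frequency table deterministically.

All generators are pure functions of the configuration: one global seed
is split into independent sub-streams per generator, so adding draws to
one generator never perturbs another's output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix, MethylationTable, SampleAnnotation, normalize_by_reference
from .ihc import INTENSITIES, PROPORTIONS, IHCRecord

log = logging.getLogger(__name__)

__all__ = [
    "PlantedMarkerSpec",
    "IHCGroupConfig",
    "SimulationConfig",
    "simulate_expression",
    "simulate_methylation",
    "simulate_ihc",
    "reference_ihc_records",
]


@dataclass(frozen=True)
class PlantedMarkerSpec:
    """A gene constructed to pass the screen in one subtype.

    ``hot_median`` is the designed median on the normalized scale in the
    hot subtype; every sample outside it is drawn uniformly below
    ``background_ceiling``.
    """

    gene_id: str
    hot_subtype: str
    hot_median: float = 15.0
    background_ceiling: float = 0.05

    def __post_init__(self) -> None:
        if self.hot_median <= 0 or self.background_ceiling <= 0:
            raise ValueError("hot_median and background_ceiling must be positive")
        if self.hot_median <= 8.0:
            log.warning(
                "planted marker %s: hot_median %.3g is at or below the default screen "
                "threshold 8; the screen is not expected to recover it",
                self.gene_id, self.hot_median,
            )
        if self.background_ceiling >= 0.15:
            log.warning(
                "planted marker %s: background_ceiling %.3g is at or above the default "
                "screen ceiling 0.15", self.gene_id, self.background_ceiling,
            )


@dataclass(frozen=True)
class IHCGroupConfig:
    """Grade distribution for one tumor type x marker group."""

    tumor_type: str
    marker: str
    n_cases: int
    probs: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        if self.n_cases < 0:
            raise ValueError("n_cases must be non-negative")
        total = 0.0
        for (inten, prop), p in self.probs.items():
            if inten not in INTENSITIES or prop not in PROPORTIONS:
                raise ValueError(f"invalid grade pair ({inten!r}, {prop!r})")
            if (inten == "negative") != (prop == "none"):
                raise ValueError(f"inconsistent grade pair ({inten!r}, {prop!r})")
            if p < 0:
                raise ValueError("category probabilities must be non-negative")
            total += p
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(
                f"category probabilities for {self.tumor_type}/{self.marker} sum to "
                f"{total!r}, not 1"
            )


def _default_markers() -> tuple[PlantedMarkerSpec, ...]:
    return tuple(
        PlantedMarkerSpec(gene_id=f"MK{i + 1:03d}", hot_subtype="chromophobe")
        for i in range(5)
    )


def _default_ihc() -> tuple[IHCGroupConfig, ...]:
    """Perfectly separating IHC tables for the first two planted markers."""
    groups = []
    for marker in ("MK001", "MK002"):
        groups.append(IHCGroupConfig("chromophobe", marker, 23, {("strong", "diffuse"): 1.0}))
        groups.append(IHCGroupConfig("clear_cell", marker, 153, {("negative", "none"): 1.0}))
        groups.append(IHCGroupConfig("papillary", marker, 10, {("negative", "none"): 1.0}))
    return tuple(groups)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror a three-subtype renal-carcinoma screen at desk
    scale: 2,000 genes, subtypes of 40/300/100 samples, five markers
    planted in the target subtype at hot-median 15 with background
    ceiling 0.05.
    """

    seed: int = 0
    subtypes: tuple[tuple[str, int], ...] = (
        ("chromophobe", 40),
        ("clear_cell", 300),
        ("papillary", 100),
    )
    n_genes: int = 2000
    reference_gene: str = "TBP"
    planted_markers: tuple[PlantedMarkerSpec, ...] = field(default_factory=_default_markers)
    # background expression: log-normal with dropout point mass at 0
    log_mean: float = 0.0
    log_sd: float = 1.0
    dropout: float = 0.3
    hot_log_sd: float = 0.2
    reference_log_median: float = math.log(10.0)
    reference_log_sd: float = 0.25
    # methylation coupling
    beta_baseline: float = 0.55
    beta_shift: float = 0.12
    beta_noise_sd: float = 0.05
    target_rho: float = -0.28  # pooled Spearman implied by the coupling defaults above
    probes_per_marker: int = 2
    n_null_probes: int = 20
    null_beta_sd: float = 0.10
    missing_rate: float = 0.01
    # immunohistochemistry
    ihc: tuple[IHCGroupConfig, ...] = field(default_factory=_default_ihc)
    ihc_exact_counts: bool = True

    def __post_init__(self) -> None:
        if self.n_genes <= len(self.planted_markers):
            raise ValueError("n_genes must exceed the number of planted markers")
        labels = [lab for lab, _ in self.subtypes]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate subtype labels")
        if len(labels) < 2:
            raise ValueError("need at least 2 subtypes")
        for lab, n in self.subtypes:
            if n < 3:
                raise ValueError(f"subtype {lab!r} has n={n}; need at least 3 samples")
        for m in self.planted_markers:
            if m.hot_subtype not in labels:
                raise ValueError(f"planted marker {m.gene_id!r}: unknown subtype {m.hot_subtype!r}")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")


def _streams(cfg: SimulationConfig) -> list[np.random.Generator]:
    """Independent generator streams: [expression, methylation, ihc]."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(cfg.seed).spawn(3)]


def _sample_ids(cfg: SimulationConfig) -> tuple[list[str], pd.Series]:
    ids, labels = [], []
    for lab, n in cfg.subtypes:
        for i in range(n):
            ids.append(f"{lab}_{i:03d}")
            labels.append(lab)
    return ids, pd.Series(labels, index=ids)


def simulate_expression(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, SampleAnnotation, set[str]]:
    """Generate a raw expression matrix, annotation, and the planted gene set.

    The reference gene is strictly positive in every sample.  After
    dividing by it, planted genes have hot-subtype values log-normal
    around ``hot_median`` and background values uniform below their
    ceiling; all other genes share one subtype-independent null
    distribution.
    """
    rng = _streams(cfg)[0]
    sample_ids, labels = _sample_ids(cfg)
    n_samples = len(sample_ids)
    is_hot = {lab: (labels == lab).to_numpy() for lab, _ in cfg.subtypes}

    ref_raw = rng.lognormal(cfg.reference_log_median, cfg.reference_log_sd, n_samples)

    planted_ids = [m.gene_id for m in cfg.planted_markers]
    rows: dict[str, np.ndarray] = {cfg.reference_gene: np.ones(n_samples)}
    for m in cfg.planted_markers:
        hot = is_hot[m.hot_subtype]
        vals = rng.uniform(0.0, m.background_ceiling, n_samples)
        vals[hot] = rng.lognormal(math.log(m.hot_median), cfg.hot_log_sd, int(hot.sum()))
        rows[m.gene_id] = vals

    n_background = cfg.n_genes - len(planted_ids) - 1
    bg = rng.lognormal(cfg.log_mean, cfg.log_sd, (n_background, n_samples))
    bg[rng.random((n_background, n_samples)) < cfg.dropout] = 0.0
    for i in range(n_background):
        rows[f"G{i + 1:05d}"] = bg[i]

    norm = pd.DataFrame(rows, index=sample_ids).T
    raw = norm * ref_raw  # broadcast per sample column
    expr = ExpressionMatrix(raw)
    ann = SampleAnnotation(labels)
    return expr, ann, set(planted_ids)


def simulate_methylation(
    cfg: SimulationConfig,
    expr: ExpressionMatrix,
    ann: SampleAnnotation,
) -> tuple[MethylationTable, pd.DataFrame]:
    """Generate beta values coupled to the planted markers' expression.

    Returns the methylation table and a two-column ``probe_id,gene_id``
    map.  Coupled probes decrease monotonically in standardized log1p
    normalized expression; null probes are independent noise around the
    baseline and are mapped to background genes.
    """
    rng = _streams(cfg)[1]
    nm = normalize_by_reference(expr, cfg.reference_gene)
    sample_ids = nm.sample_ids
    n = len(sample_ids)

    probe_rows: dict[str, np.ndarray] = {}
    mapping: list[tuple[str, str]] = []
    k = 0
    for m in cfg.planted_markers:
        e = nm.values.loc[m.gene_id].to_numpy()
        z = np.log1p(e)
        z = (z - z.mean()) / z.std()
        for _ in range(cfg.probes_per_marker):
            k += 1
            probe = f"cg{k:08d}"
            beta = np.clip(
                cfg.beta_baseline - cfg.beta_shift * z + rng.normal(0, cfg.beta_noise_sd, n),
                0.0, 1.0,
            )
            probe_rows[probe] = beta
            mapping.append((probe, m.gene_id))

    background_genes = [g for g in nm.gene_ids
                        if g != cfg.reference_gene and g not in {m.gene_id for m in cfg.planted_markers}]
    for j in range(cfg.n_null_probes):
        k += 1
        probe = f"cg{k:08d}"
        beta = np.clip(cfg.beta_baseline + rng.normal(0, cfg.null_beta_sd, n), 0.0, 1.0)
        probe_rows[probe] = beta
        mapping.append((probe, background_genes[j % len(background_genes)]))

    beta_df = pd.DataFrame(probe_rows, index=sample_ids).T
    if cfg.missing_rate > 0:
        miss = rng.random(beta_df.shape) < cfg.missing_rate
        beta_df = beta_df.mask(miss)
    table = MethylationTable(beta_df)
    probe_gene = pd.DataFrame(mapping, columns=["probe_id", "gene_id"])
    return table, probe_gene


def _apportion(n: int, probs: list[float]) -> list[int]:
    """Largest-remainder apportionment of n cases over category probabilities."""
    quotas = [n * p for p in probs]
    counts = [int(math.floor(q)) for q in quotas]
    remainder = n - sum(counts)
    order = sorted(range(len(probs)), key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def simulate_ihc(cfg: SimulationConfig) -> list[IHCRecord]:
    """Generate one graded record per case x marker.

    With ``ihc_exact_counts`` (default) the per-group category counts
    match the configured probabilities exactly via largest-remainder
    apportionment; otherwise categories are drawn multinomially.
    """
    rng = _streams(cfg)[2]
    records: list[IHCRecord] = []
    for group in cfg.ihc:
        cats = sorted(group.probs)  # deterministic category order
        probs = [group.probs[c] for c in cats]
        if cfg.ihc_exact_counts:
            counts = _apportion(group.n_cases, probs)
        else:
            counts = list(rng.multinomial(group.n_cases, probs))
        i = 0
        for cat, cnt in zip(cats, counts):
            for _ in range(cnt):
                records.append(
                    IHCRecord(
                        case_id=f"{group.tumor_type}_{i:03d}",
                        tumor_type=group.tumor_type,
                        marker=group.marker,
                        intensity=cat[0],
                        proportion=cat[1],
                    )
                )
                i += 1
    return records


def reference_ihc_records() -> list[IHCRecord]:
    """The published BSND/ATP6V1G3 immunoreactivity table for renal tumors.

    Encodes the reported grade frequencies across 200 renal tumors
    (23 chromophobe RCC, 153 clear cell RCC, 10 papillary RCC, 14 renal
    oncocytoma): strong diffuse staining of both markers in every
    chromophobe case and in 13/14 oncocytomas; BSND negative in all
    clear cell and papillary cases; ATP6V1G3 weakly positive in 8/153
    clear cell and 1/10 papillary cases (the published counts do not
    split the weak cases between diffuse and partial extent; both grades
    are represented, which no built-in rule distinguishes).
    """
    neg = {("negative", "none"): 1.0}
    sd = {("strong", "diffuse"): 1.0}
    onco = {("strong", "diffuse"): 13 / 14, ("negative", "none"): 1 / 14}
    groups = [
        IHCGroupConfig("chromophobe", "BSND", 23, sd),
        IHCGroupConfig("clear_cell", "BSND", 153, neg),
        IHCGroupConfig("papillary", "BSND", 10, neg),
        IHCGroupConfig("oncocytoma", "BSND", 14, onco),
        IHCGroupConfig("chromophobe", "ATP6V1G3", 23, sd),
        IHCGroupConfig(
            "clear_cell", "ATP6V1G3", 153,
            {("negative", "none"): 145 / 153, ("weak", "diffuse"): 4 / 153,
             ("weak", "partial"): 4 / 153},
        ),
        IHCGroupConfig(
            "papillary", "ATP6V1G3", 10,
            {("negative", "none"): 9 / 10, ("weak", "partial"): 1 / 10},
        ),
        IHCGroupConfig("oncocytoma", "ATP6V1G3", 14, onco),
    ]
    cfg = SimulationConfig(ihc=tuple(groups), ihc_exact_counts=True)
    return simulate_ihc(cfg)
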