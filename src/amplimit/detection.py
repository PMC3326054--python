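"""Detection limits for amplicon surveys.

The question this module answers: how many reads must be sequenced to observe
a taxon of relative abundance p at least once, with stated confidence?  Under
independent sampling the number of reads until first observation is geometric,
so the probability of detection within k reads is

    F(k; p) = 1 - (1 - p)^k

and the depth required for detection with confidence c is the smallest k with
F(k; p) >= c, i.e. ceil(ln(1-c) / ln(1-p)).  Inverting at a fixed depth k
gives the minimum detectable abundance p* = 1 - (1-c)^(1/k) — the abundance
cutoff below which observed taxa are as likely spurious as real, used by
:mod:`amplimit.filtering` to screen contaminants.

Empirical detection probabilities come from multiple rarefaction: repeated
subsampling of a deep library without replacement, recording per taxon the
fraction of subsamples containing it at each depth.  Agreement between the
empirical curve and the geometric model is scored with a bootstrapped
Kolmogorov-Smirnov statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DetectionCurve",
    "GeometricDetectionModel",
    "default_levels",
    "multiple_rarefaction",
    "geometric_detection_cdf",
    "reads_required",
    "min_detectable_abundance",
    "bootstrap_ks_test",
    "fit_threshold_power_law",
]


@dataclass
class DetectionCurve:
    """Per-taxon empirical detection proportion versus subsampling depth."""

    taxon_id: str
    levels: list[int]
    proportions: list[float]
    n_subsamples: int = 100

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.proportions):
            raise ValueError("levels and proportions differ in length")
        lv = np.asarray(self.levels)
        if lv.size and (np.any(np.diff(lv) <= 0) or lv[0] <= 0):
            raise ValueError("levels must be strictly increasing and positive")
        pr = np.asarray(self.proportions)
        if pr.size and (pr.min() < 0 or pr.max() > 1):
            raise ValueError("proportions must lie in [0, 1]")


@dataclass(frozen=True)
class GeometricDetectionModel:
    """Geometric detection model with success probability p.

    ``p`` is the taxon's relative abundance (the chance one sequenced read
    belongs to it); ``confidence`` is the detection confidence used for
    depth/abundance cutoffs.
    """

    p: float
    confidence: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 < self.p <= 1.0:
            raise ValueError("p must be in (0, 1]")
        if not 0.0 < self.confidence < 1.0:
            raise ValueError("confidence must be in (0, 1)")

    def cdf(self, k: int | np.ndarray) -> float | np.ndarray:
        return geometric_detection_cdf(self.p, k)

    def reads_required(self) -> int:
        return reads_required(self.p, self.confidence)


def geometric_detection_cdf(
    p: float, k: int | np.ndarray
) -> float | np.ndarray:
    """P(taxon of abundance p seen at least once in k reads) = 1-(1-p)^k."""
    if not 0.0 < p <= 1.0:
        raise ValueError("p must be in (0, 1]")
    karr = np.asarray(k)
    if np.any(karr < 0):
        raise ValueError("k must be non-negative")
    out = -np.expm1(karr * np.log1p(-p)) if p < 1.0 else (karr > 0) * 1.0
    return float(out) if np.isscalar(k) else np.asarray(out, dtype=float)


def reads_required(p: float, confidence: float = 0.95) -> int:
    """Smallest depth k with detection probability >= ``confidence``.

    Closed form ceil(ln(1-c)/ln(1-p)), then nudged so that the invariant
    F(k) >= c > F(k-1) holds exactly in floating point.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError("p must be in (0, 1]")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    if p == 1.0:
        return 1
    k = max(1, math.ceil(math.log(1.0 - confidence) / math.log1p(-p)) - 2)
    while geometric_detection_cdf(p, k) < confidence:
        k += 1
    return k


def min_detectable_abundance(k: int, confidence: float = 0.95) -> float:
    """Abundance p* whose required depth at ``confidence`` is exactly k.

    p* = 1 - (1-c)^(1/k); taxa rarer than p* are expected to escape detection
    at depth k more often than (1-c) of the time.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    return -math.expm1(math.log(1.0 - confidence) / k)


def default_levels(library_size: int | None = None) -> list[int]:
    """The standard multiple-rarefaction depth grid.

    10..100 step 10, 100..1,000 step 100, 1,000..10,000 step 1,000, and
    10,000..90,000 step 10,000; duplicates removed and, if ``library_size``
    is given, levels above it dropped.
    """
    grid: list[int] = []
    for start, stop, step in (
        (10, 100, 10),
        (100, 1000, 100),
        (1000, 10_000, 1000),
        (10_000, 90_000, 10_000),
    ):
        grid.extend(range(start, stop + step, step))
    levels = sorted(set(grid))
    if library_size is not None:
        levels = [k for k in levels if k <= library_size]
    return levels


def multiple_rarefaction(
    library_counts: dict[str, int],
    levels: list[int] | None = None,
    n_subsamples: int = 100,
    seed: int | np.random.Generator = 0,
) -> list[DetectionCurve]:
    """Empirical detection curves by repeated subsampling without replacement.

    For each depth k, ``n_subsamples`` subsamples of size k are drawn without
    replacement from the pooled library; a taxon's detection proportion at k
    is the fraction of subsamples containing at least one of its reads.
    """
    if n_subsamples < 1:
        raise ValueError("n_subsamples must be >= 1")
    taxa = list(library_counts)
    counts = np.array([library_counts[t] for t in taxa], dtype=np.int64)
    if np.any(counts < 0):
        raise ValueError("negative counts")
    total = int(counts.sum())
    if levels is None:
        levels = default_levels(total)
    for k in levels:
        if k > total:
            raise ValueError(
                f"rarefaction level {k} exceeds library size {total}"
            )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    detected = np.zeros((len(levels), len(taxa)))
    for li, k in enumerate(levels):
        for _ in range(n_subsamples):
            sub = rng.multivariate_hypergeometric(counts, k)
            detected[li] += sub > 0
    props = detected / n_subsamples
    return [
        DetectionCurve(
            taxon_id=t,
            levels=list(levels),
            proportions=list(props[:, ti]),
            n_subsamples=n_subsamples,
        )
        for ti, t in enumerate(taxa)
    ]


def bootstrap_ks_test(
    curve: DetectionCurve,
    model: GeometricDetectionModel,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Bootstrapped Kolmogorov-Smirnov fit of a detection curve to the model.

    The observed statistic is D = max_k |Fhat(k) - F(k; p)|.  Bootstrap
    replicates re-draw the ``n_subsamples`` Bernoulli detections at each level
    from Fhat and measure D* = max_k |Fhat*(k) - Fhat(k)|, the sampling
    variability of the curve; the p-value is
    (1 + #{D* >= D}) / (n_boot + 1), so a D large relative to subsampling
    noise is evidence against the geometric model.
    """
    if not curve.levels:
        raise ValueError("empty detection curve")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    levels = np.asarray(curve.levels)
    fhat = np.asarray(curve.proportions)
    theory = geometric_detection_cdf(model.p, levels)
    d_obs = float(np.max(np.abs(fhat - theory)))
    n = curve.n_subsamples
    boot = rng.binomial(n, fhat, size=(n_boot, fhat.size)) / n
    d_boot = np.max(np.abs(boot - fhat), axis=1)
    p_value = (1.0 + np.count_nonzero(d_boot >= d_obs)) / (n_boot + 1.0)
    return d_obs, float(p_value)


def fit_threshold_power_law(
    abundances: list[float] | np.ndarray,
    required_reads: list[int] | np.ndarray,
) -> tuple[float, float, float]:
    """Power-law fit N = a * p^b to (abundance, required depth) pairs.

    Ordinary least squares in log-log space; returns (a, b, R^2) with R^2
    computed on log N.  For exact geometric thresholds b is close to -1 and
    a close to -ln(1-confidence).
    """
    p = np.asarray(abundances, dtype=float)
    n = np.asarray(required_reads, dtype=float)
    if p.size != n.size or p.size < 3:
        raise ValueError("need at least 3 matched (abundance, reads) pairs")
    if np.any(p <= 0) or np.any(n <= 0):
        raise ValueError("abundances and read counts must be positive")
    order = np.lexsort((n, p))  # input order must not perturb the fit
    p, n = p[order], n[order]
    x, y = np.log(p), np.log(n)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return float(np.exp(intercept)), float(slope), r2
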