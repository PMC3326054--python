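"""Abundance cutoffs and contaminant classification.

Applies the detection-limit logic to real tables: rarefy samples to a common
depth, zero out taxa below a relative-abundance cutoff (the minimum abundance
detectable with confidence at that depth), split observed genera into
expected versus contaminant against a known composition, and quantify how
contamination scales with DNA yield.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detection import fit_threshold_power_law
from .otu_table import OTUTable

__all__ = [
    "ContaminationReport",
    "normalize_to_depth",
    "apply_abundance_cutoff",
    "classify_contaminants",
    "fit_yield_contamination_power_law",
]


@dataclass
class ContaminationReport:
    """Per-sample partition of observed genera into expected vs contaminant.

    ``contaminant_fraction`` is the fraction of reads carried by contaminant
    genera; ``dna_yield`` (ng/uL) is optional metadata for yield-contamination
    regressions.
    """

    expected_taxa: dict[str, list[str]]
    contaminant_taxa: dict[str, list[str]]
    contaminant_fraction: dict[str, float]
    n_contaminant_genera: dict[str, int]
    dna_yield: dict[str, float] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.contaminant_fraction)


def normalize_to_depth(
    table: OTUTable, depth: int, seed: int | np.random.Generator = 0
) -> OTUTable:
    """Rarefy every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads are dropped with a warning.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    totals = table.sample_totals()
    keep = [s for s in table.sample_ids if totals[s] >= depth]
    dropped = sorted(set(table.sample_ids) - set(keep))
    if dropped:
        warnings.warn(
            f"dropping samples below depth {depth}: {', '.join(dropped)}",
            stacklevel=2,
        )
    out = {}
    for s in keep:
        col = table.counts[s].to_numpy()
        if totals[s] == depth:
            out[s] = col
        else:
            out[s] = rng.multivariate_hypergeometric(col, depth)
    df = pd.DataFrame(out, index=table.counts.index, dtype=np.int64)
    return OTUTable(counts=df, genus=dict(table.genus), normalized_depth=depth)


def apply_abundance_cutoff(table: OTUTable, cutoff: float) -> OTUTable:
    """Zero, per sample, every taxon below ``cutoff`` relative abundance.

    Comparison is strict (a taxon at exactly the cutoff is retained); taxa
    zeroed in every sample are dropped from the table.  Counts are not
    renormalized — totals shrink by the removed reads.  The input table is
    left unmodified.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must be in [0, 1]")
    counts = table.counts.copy()
    totals = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = counts.to_numpy() / totals.to_numpy()
    filtered = counts.to_numpy().copy()
    filtered[np.nan_to_num(rel) < cutoff] = 0
    df = pd.DataFrame(filtered, index=counts.index, columns=counts.columns)
    df = df.loc[df.sum(axis=1) > 0]
    return OTUTable(
        counts=df,
        genus={t: g for t, g in table.genus.items() if t in df.index},
        normalized_depth=None,
    )


def classify_contaminants(
    table: OTUTable,
    expected_genera: set[str],
    dna_yield: dict[str, float] | None = None,
) -> ContaminationReport:
    """Partition observed genera into expected vs bona fide contaminants.

    Counts are first consolidated at genus level; any genus outside
    ``expected_genera`` observed in a sample is a contaminant there.  The
    contaminant fraction is contaminant reads / total reads per sample.
    """
    if not expected_genera:
        raise ValueError("expected_genera must be non-empty")
    by_genus = table.collapse_genus()
    expected: dict[str, list[str]] = {}
    contaminant: dict[str, list[str]] = {}
    fraction: dict[str, float] = {}
    n_genera: dict[str, int] = {}
    for s in by_genus.sample_ids:
        col = by_genus.counts[s]
        observed = col[col > 0]
        exp = sorted(g for g in observed.index if g in expected_genera)
        con = sorted(g for g in observed.index if g not in expected_genera)
        total = int(col.sum())
        con_reads = int(observed[con].sum()) if con else 0
        expected[s] = exp
        contaminant[s] = con
        fraction[s] = con_reads / total if total else 0.0
        n_genera[s] = len(con)
    return ContaminationReport(
        expected_taxa=expected,
        contaminant_taxa=contaminant,
        contaminant_fraction=fraction,
        n_contaminant_genera=n_genera,
        dna_yield=dict(dna_yield or {}),
    )


def fit_yield_contamination_power_law(
    yields: list[float] | np.ndarray,
    contaminant_fractions: list[float] | np.ndarray,
) -> tuple[float, float, float]:
    """Power-law fit fraction = a * yield^b (log-log least squares).

    A negative exponent b reproduces the usual pattern: lower DNA yield,
    higher reagent-contaminant share.
    """
    return fit_threshold_power_law(yields, contaminant_fractions)
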