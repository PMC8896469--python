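"""Enrichment-factor calibration, cells-analyzed accounting and mutation rates.

The digestion step removes most wild-type (site-bearing, *sensitive*)
molecules; to keep the rate denominator honest, every sample is run as two
mixtures spiked with digestion-*resistant* plasmid molecules.  The treated
mixture is digested; the untreated mixture contains a known fraction
``f_D`` of the DNA (default 5%) and ``f_S`` times the spike-in volume
(default 6x).  The enrichment factor is then the mix-corrected ratio of
sensitive-to-resistant ratios,

    E = (f_S / f_D) * (S_u / R_u) / (S_t / R_t),

the fold-depletion of digestible molecules.  The number of cells analyzed
-- the exposure denominator of every rate -- is N = E * W + M, with W and M
the wild-type and mutant molecules called by consensus in the treated
library.  Per-mutation rates are x / N with exact Clopper-Pearson 95%
intervals (evaluated on the Poisson/gamma path at these exposures).
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from . import stats as _stats
from .refmodel import ROIModel, MutationEvent

__all__ = [
    "EnrichmentExperiment",
    "RateEstimate",
    "enrichment_factor",
    "cells_analyzed",
    "mutation_rate",
    "aggregate_rates",
    "pool",
    "rate_table",
]


@dataclass(frozen=True)
class EnrichmentExperiment:
    """Treated/untreated sensitive & resistant molecule counts plus the known
    mix parameters of the two-mixture spike-in design."""

    S_t: int
    R_t: int
    S_u: int
    R_u: int
    dna_fraction_untreated: float = 0.05  # f_D
    spike_factor_untreated: float = 6.0  # f_S

    def __post_init__(self) -> None:
        if min(self.S_t, self.R_t, self.S_u, self.R_u) < 0:
            raise ValueError("molecule counts must be non-negative")
        if self.dna_fraction_untreated <= 0 or self.spike_factor_untreated <= 0:
            raise ValueError("mix parameters must be positive")

    @property
    def mix_correction(self) -> float:
        return self.spike_factor_untreated / self.dna_fraction_untreated


class UndefinedEnrichment(ValueError):
    """Raised when a zero count makes the enrichment factor undefined."""


def enrichment_factor(exp: EnrichmentExperiment) -> float:
    """E = (f_S/f_D) * (S_u/R_u) / (S_t/R_t): fold-depletion of sensitive
    molecules, equivalently the enrichment of digestion-protected mutants."""
    if exp.R_t == 0 or exp.R_u == 0 or exp.S_t == 0:
        raise UndefinedEnrichment(
            f"zero count makes E undefined: S_t={exp.S_t} R_t={exp.R_t} "
            f"S_u={exp.S_u} R_u={exp.R_u}"
        )
    return exp.mix_correction * (exp.S_u / exp.R_u) / (exp.S_t / exp.R_t)


def enrichment_factor_se(exp: EnrichmentExperiment) -> float:
    """Delta-method standard error of E treating the four counts as
    independent Poisson draws (a Monte-Carlo sampling band for recovery
    checks, not an input to the rate CIs)."""
    E = enrichment_factor(exp)
    rel_var = sum(1.0 / c for c in (exp.S_t, exp.R_t, exp.S_u, exp.R_u) if c > 0)
    return E * math.sqrt(rel_var)


def cells_analyzed(E: float, W: int, M: int) -> float:
    """N = E*W + M: enrichment factor times wild-type molecules called,
    plus the (small) number of mutant molecules called."""
    if W < 0 or M < 0:
        raise ValueError("molecule counts must be non-negative")
    if E < 1:
        warnings.warn(f"enrichment factor {E:.3g} < 1 suggests digestion failure", stacklevel=2)
    return E * W + M


@dataclass(frozen=True)
class RateEstimate:
    """A per-mutation (or aggregate) de novo rate with its exact CI."""

    label: str
    count: int
    exposure: float  # genomes
    rate: float
    ci95: tuple[float, float]
    expected_rate: float | None = None

    @property
    def fold_vs_expected(self) -> float | None:
        if self.expected_rate is None or self.expected_rate <= 0:
            return None
        return self.rate / self.expected_rate


def mutation_rate(
    x: int,
    N: float,
    conf: float = 0.95,
    label: str = "",
    expected_rate: float | None = None,
) -> RateEstimate:
    """Point rate x/N with the Clopper-Pearson exact interval for x events
    in round(N) genomes.  N is treated as a known constant (the enrichment
    calibration is designed so that it is a function of precisely known
    quantities)."""
    if N <= 0:
        raise ValueError("exposure N must be positive")
    if not 0 <= x <= N:
        raise ValueError("need 0 <= x <= N")
    ci = _stats.binom_exact_ci(x, int(round(N)), conf)
    return RateEstimate(label, x, N, x / N, ci, expected_rate)


def aggregate_rates(
    tallies: Counter | dict,
    roi: ROIModel,
    N: float,
    expected_point_rate: float | None = None,
    expected_indel_rate: float | None = None,
    observability_correction: bool = False,
) -> dict:
    """ROI-level aggregate rates from per-mutation-name tallies.

    ``avg_point_per_base`` divides the summed point counts by N times the
    number of informative positions (site positions carrying at least one
    observable SNV; 6 for the study ROIs -- the degenerate position is not
    informative).  ``indel_per_roi`` is the summed indel count over N.
    The optional observability correction multiplies the per-base point
    rate by (3 * informative positions) / |observable SNVs| to compensate
    for artifact-class exclusions; it is off by default.
    """
    from .refmodel import enumerate_observable_point_mutations

    observable = enumerate_observable_point_mutations(roi)
    informative = sorted({ev.start for ev in observable})
    L = len(informative)
    if L == 0:
        raise ValueError("ROI has no informative positions")
    point = 0
    indel = 0
    per_position: Counter = Counter()
    for name, n in tallies.items():
        if "del" in name or "ins" in name:
            indel += n
        else:
            point += n
            pos = int("".join(ch for ch in name if ch.isdigit()))
            per_position[pos] += n
    avg_point = point / (N * L)
    if observability_correction:
        avg_point *= (3 * L) / len(observable)
    out = {
        "avg_point_per_base": mutation_rate(
            point, N * L, label="avg_point_per_base", expected_rate=expected_point_rate
        ),
        "indel_per_roi": mutation_rate(
            indel, N, label="indel_per_roi", expected_rate=expected_indel_rate
        ),
        "per_position": {
            pos: mutation_rate(per_position.get(pos, 0), N, label=f"pos{pos}")
            for pos in informative
        },
        "informative_positions": informative,
    }
    if observability_correction:
        out["avg_point_per_base_corrected"] = avg_point
    return out


def pool(samples: list):
    """Pool per-sample (tallies, exposure[, gene]) tuples: counts and
    exposures sum; rate estimates should be recomputed from the pooled sums.

    When gene labels are supplied they must agree across samples -- pooling
    different ROIs is a coordinate-system error, not a statistics question.
    """
    if not samples:
        raise ValueError("cannot pool an empty sample list")
    total: Counter = Counter()
    N = 0.0
    genes = set()
    for item in samples:
        tallies, n = item[0], item[1]
        if len(item) > 2:
            genes.add(item[2])
        total.update(tallies)
        N += n
    if len(genes) > 1:
        raise ValueError(f"cannot pool across genes: {sorted(genes)}")
    return total, N


def rate_table(estimates: list[RateEstimate], group: str = "", gene: str = "") -> pd.DataFrame:
    rows = [
        {
            "group": group,
            "gene": gene,
            "mutation": r.label,
            "x": r.count,
            "N": r.exposure,
            "rate": r.rate,
            "ci_lo": r.ci95[0],
            "ci_hi": r.ci95[1],
            "expected": r.expected_rate,
            "fold": r.fold_vs_expected,
        }
        for r in estimates
    ]
    return pd.DataFrame(
        rows,
        columns=["group", "gene", "mutation", "x", "N", "rate", "ci_lo", "ci_hi", "expected", "fold"],
    )
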