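"""Simulated null distribution of FST/G'ST and outlier classification.

Each null replicate is one locus pushed through the full pipeline:
isolation-model genealogy -> infinite-sites mutations -> stepwise-model
allele states -> two-deme differentiation statistic.  Replicates that come
out monomorphic are tracked as undefined and excluded from the percentile
cutoffs; their rate is reported.

Cutoffs are inverse-ECDF (type 1) order statistics of the simulated
values.  Two tail conventions are provided: ``central95`` (2.5% in each
tail, total nominal rate 5%) and ``tail5`` (5% in each tail).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import ceil, isnan, nan
from typing import Literal, Sequence

import numpy as np

from .coalescent import IsolationModel, drop_mutations, simulate_genealogy
from .exceptions import ModelError, ParameterError
from .microsat import assign_steps, haplotypes_to_alleles
from .popstats import LocusStat, fst_wc, gst_prime

__all__ = [
    "NullDistribution",
    "LocusCall",
    "OutlierReport",
    "simulate_null_statistic",
    "build_null",
    "classify_loci",
    "sensitivity_rescan",
]

TailMode = Literal["central95", "tail5"]

_STATS = {"fst": fst_wc, "gst_prime": gst_prime}

_TAIL_MASS = {"central95": 0.025, "tail5": 0.05}


def _quantile_type1(sorted_values: np.ndarray, q: float) -> float:
    """Inverse-ECDF quantile: the ceil(q*m)-th order statistic."""
    m = len(sorted_values)
    idx = min(max(ceil(q * m) - 1, 0), m - 1)
    return float(sorted_values[idx])


@dataclass
class NullDistribution:
    """Simulated per-locus statistic values and their percentile cutoffs."""

    statistic: str
    values: np.ndarray  # finite values only, one per defined replicate
    n_undefined: int
    model: IsolationModel
    tail_mode: TailMode
    lower: float
    upper: float

    @property
    def replicates(self) -> int:
        return len(self.values) + self.n_undefined

    @property
    def undefined_rate(self) -> float:
        return self.n_undefined / self.replicates


@dataclass(frozen=True)
class LocusCall:
    name: str
    value: float
    call: str  # low | high | none | undefined


@dataclass
class OutlierReport:
    statistic: str
    tail_mode: TailMode
    calls: list[LocusCall]
    model: IsolationModel
    lower: float
    upper: float

    @property
    def n_low(self) -> int:
        return sum(1 for c in self.calls if c.call == "low")

    @property
    def n_high(self) -> int:
        return sum(1 for c in self.calls if c.call == "high")

    @property
    def n_undefined(self) -> int:
        return sum(1 for c in self.calls if c.call == "undefined")


def simulate_null_statistic(
    model: IsolationModel, statistic: str, rng: np.random.Generator
) -> float:
    """One null replicate: simulate a locus, convert to microsatellite
    alleles, return the deme-1-vs-deme-2 statistic (NaN if monomorphic)."""
    stat_fn = _STATS[statistic]
    tree = simulate_genealogy(model, rng)
    locus = drop_mutations(tree, model.theta, rng)
    steps = assign_steps(locus.site_count, rng)
    sample = haplotypes_to_alleles(locus, steps)
    counts = sample.deme_allele_counts()
    if counts.shape[1] < 2:
        return nan
    return stat_fn(counts)


def build_null(
    model: IsolationModel,
    replicates: int,
    statistic: str = "fst",
    tail_mode: TailMode = "central95",
    rng: np.random.Generator | None = None,
) -> NullDistribution:
    """Simulate ``replicates`` independent loci and fix percentile cutoffs.

    The study's configuration is theta=4, n1=n2=200, tau=1.25 and 10 000
    replicates.
    """
    if replicates < 100:
        raise ParameterError(f"need >= 100 replicates, got {replicates}")
    if statistic not in _STATS:
        raise ParameterError(f"statistic must be one of {sorted(_STATS)}")
    if tail_mode not in _TAIL_MASS:
        raise ParameterError(f"tail_mode must be one of {sorted(_TAIL_MASS)}")
    rng = np.random.default_rng() if rng is None else rng
    raw = np.fromiter(
        (simulate_null_statistic(model, statistic, rng) for _ in range(replicates)),
        dtype=float,
        count=replicates,
    )
    values = raw[~np.isnan(raw)]
    n_undef = replicates - len(values)
    if n_undef > 0.5 * replicates:
        raise ModelError(
            f"{n_undef}/{replicates} null replicates monomorphic; "
            "model yields too little variation"
        )
    srt = np.sort(values)
    m = _TAIL_MASS[tail_mode]
    return NullDistribution(
        statistic=statistic,
        values=values,
        n_undefined=n_undef,
        model=model,
        tail_mode=tail_mode,
        lower=_quantile_type1(srt, m),
        upper=_quantile_type1(srt, 1.0 - m),
    )


def classify_loci(
    observed: Sequence[LocusStat], null: NullDistribution
) -> OutlierReport:
    """Call each observed locus low/high/none against the null cutoffs.

    Loci with an undefined statistic (e.g. fixed for the same allele in
    both species) are flagged ``undefined`` and excluded from the counts.
    """
    if not observed:
        raise ParameterError("no observed loci supplied")
    calls = []
    for stat in observed:
        value = getattr(stat, null.statistic)
        if isnan(value):
            call = "undefined"
        elif value < null.lower:
            call = "low"
        elif value > null.upper:
            call = "high"
        else:
            call = "none"
        calls.append(LocusCall(name=stat.name, value=value, call=call))
    return OutlierReport(
        statistic=null.statistic,
        tail_mode=null.tail_mode,
        calls=calls,
        model=null.model,
        lower=null.lower,
        upper=null.upper,
    )


def sensitivity_rescan(
    observed: Sequence[LocusStat],
    model: IsolationModel,
    tau_grid: Sequence[float],
    replicates: int,
    statistic: str = "fst",
    tail_mode: TailMode = "central95",
    rng: np.random.Generator | None = None,
) -> dict[float, OutlierReport]:
    """Re-run the outlier scan across a grid of split times (e.g. the 95%
    confidence bounds of the species divergence time), same observed data."""
    if len(tau_grid) == 0:
        raise ParameterError("tau grid must be non-empty")
    rng = np.random.default_rng() if rng is None else rng
    out = {}
    for tau in tau_grid:
        null = build_null(
            replace(model, tau=tau), replicates, statistic, tail_mode, rng
        )
        out[float(tau)] = classify_loci(observed, null)
    return out
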