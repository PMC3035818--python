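"""Stepwise-mutation-model conversion of infinite-sites haplotypes to
microsatellite allele states.

Each segregating site of a simulated locus is reinterpreted as a single
repeat-unit mutation of +1 or -1 (equiprobable, seed-controlled); a
chromosome's allele is the baseline plus the signed sum of the mutations it
carries.  Distinct mutation paths may collide on the same allele state —
that homoplasy is the point of the conversion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coalescent import SimulatedLocus
from .exceptions import ParameterError

__all__ = ["MsatLocusSample", "assign_steps", "haplotypes_to_alleles"]


@dataclass
class MsatLocusSample:
    """Microsatellite allele state per chromosome at one simulated locus.

    ``alleles`` are integer repeat counts relative to an arbitrary
    baseline; all downstream differentiation statistics are invariant to
    the baseline offset.  ``deme_of`` maps each chromosome to its deme.
    """

    alleles: np.ndarray
    deme_of: np.ndarray

    def deme_allele_counts(self) -> np.ndarray:
        """(deme x allele) count matrix over the observed allele range."""
        lo = int(self.alleles.min())
        width = int(self.alleles.max()) - lo + 1
        n_demes = int(self.deme_of.max()) + 1
        counts = np.zeros((n_demes, width), dtype=np.int64)
        np.add.at(counts, (self.deme_of, self.alleles - lo), 1)
        return counts


def assign_steps(site_count: int, rng: np.random.Generator) -> np.ndarray:
    """Independent equiprobable +/-1 repeat-unit step per segregating site."""
    if site_count < 0:
        raise ParameterError(f"site_count must be >= 0, got {site_count}")
    return (rng.integers(0, 2, size=site_count, dtype=np.int64) * 2 - 1)


def haplotypes_to_alleles(
    locus: SimulatedLocus, steps: np.ndarray, baseline: int = 0
) -> MsatLocusSample:
    """Collapse a 0/1 incidence matrix into allele states.

    Chromosome ``c`` gets ``baseline + sum_s incidence[c, s] * steps[s]``.
    """
    steps = np.asarray(steps, dtype=np.int64)
    if steps.shape != (locus.site_count,):
        raise ParameterError(
            f"expected {locus.site_count} steps, got shape {steps.shape}"
        )
    if locus.site_count:
        alleles = baseline + locus.incidence.astype(np.int64) @ steps
    else:
        alleles = np.full(locus.tree.n_leaves, baseline, dtype=np.int64)
    return MsatLocusSample(alleles=alleles, deme_of=locus.tree.deme.astype(np.intp))
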