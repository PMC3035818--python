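"""Microsatellite summary and differentiation statistics.

Estimator choices
-----------------
* FST is the Weir & Cockerham (1984) variance-components estimator in its
  haploid (allele-copy) form, summed over alleles, so that observed diploid
  tables and simulated haploid chromosomes are directly comparable.
  Negative values are retained — truncating them would distort the lower
  tail of a simulated null, which is exactly the region of interest for
  introgression scans.
* GST' is Hedrick's (2005) standardized GST:
  G'ST = GST * (k - 1 + HS) / ((k - 1) (1 - HS)) with k demes, HS the
  (by default unweighted) mean within-deme expected heterozygosity and HT
  the heterozygosity of the mean allele frequencies.
* Allelic richness is hypergeometric rarefaction to a standard number of
  allele copies g: E[A_g] = sum_i (1 - C(N - N_i, g) / C(N, g)).
* Inbred isofemale lines are handled by the allele-drop correction: each
  statistic is averaged over replicate data sets in which every
  heterozygous genotype of an inbred-flagged individual is reduced to one
  uniformly chosen allele.
* Collections are compared via the proportion-of-shared-alleles distance
  on pooled group frequencies, summarized by a neighbour-joining tree
  with locus-bootstrap bipartition support.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, isnan, nan
from typing import Callable, Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj as _skbio_nj

from .exceptions import ParameterError, SampleSizeError, StatisticError
from .genotypes import GenotypeTable, Individual, counts_matrix

__all__ = [
    "LocusStat",
    "expected_heterozygosity",
    "fst_wc",
    "fst_wc_multilocus",
    "gst",
    "gst_prime",
    "rarefied_allelic_richness",
    "inbred_drop_mean",
    "drop_inbred_alleles",
    "per_locus_stats",
    "dps_distance_matrix",
    "nj_tree",
    "bootstrap_support",
    "tree_bipartitions",
]


@dataclass(frozen=True)
class LocusStat:
    """Per-locus differentiation summary (the Fig-4-style scatter row)."""

    name: str
    chromosome: str
    He: float
    fst: float
    gst_prime: float
    allele_count: int


def expected_heterozygosity(freqs: Sequence[float]) -> float:
    """He = 1 - sum p_a^2 for an allele-frequency vector."""
    p = np.asarray(freqs, dtype=float)
    if (p < 0).any():
        raise ParameterError("allele frequencies must be nonnegative")
    if p.size and not np.isclose(p.sum(), 1.0):
        raise ParameterError(f"allele frequencies must sum to 1, got {p.sum()}")
    return float(1.0 - np.sum(p**2))


def _validated_counts(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if c.ndim != 2 or c.shape[0] < 2:
        raise ParameterError("need a (demes x alleles) count matrix with >= 2 demes")
    if (c < 0).any():
        raise ParameterError("allele counts must be nonnegative")
    if (c.sum(axis=1) < 2).any():
        raise SampleSizeError("each deme needs >= 2 allele copies")
    return c


def _wc_components(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-allele among-deme (MSP) and within-deme (MSG) mean squares plus
    the n_c sample-size coefficient of the haploid W&C estimator."""
    n_i = counts.sum(axis=1)
    n_tot = n_i.sum()
    r = counts.shape[0]
    p = counts / n_i[:, None]
    pbar = counts.sum(axis=0) / n_tot
    n_c = (n_tot - float((n_i**2).sum()) / n_tot) / (r - 1)
    msp = (n_i[:, None] * (p - pbar) ** 2).sum(axis=0) / (r - 1)
    msg = (n_i[:, None] * p * (1.0 - p)).sum(axis=0) / (n_tot - r)
    return msp, msg, n_c


def fst_wc(counts) -> float:
    """Weir-Cockerham theta-hat on a (demes x alleles) allele-copy count
    matrix, multi-allelic form, negatives retained.

    Returns NaN when the pooled sample is monomorphic (the statistic is
    undefined, e.g. the 4th-chromosome locus fixed in both species).
    """
    c = _validated_counts(counts)
    if (c.sum(axis=0) > 0).sum() < 2:
        return nan
    msp, msg, n_c = _wc_components(c)
    den = float((msp + (n_c - 1.0) * msg).sum())
    if den == 0.0:
        return nan
    return float((msp - msg).sum() / den)


def fst_wc_multilocus(counts_per_locus: Sequence) -> float:
    """Multi-locus W&C estimate: variance components summed over loci and
    alleles before forming the ratio.  Monomorphic loci contribute zero to
    both sums."""
    num = 0.0
    den = 0.0
    for counts in counts_per_locus:
        c = _validated_counts(counts)
        if (c.sum(axis=0) > 0).sum() < 2:
            continue
        msp, msg, n_c = _wc_components(c)
        num += float((msp - msg).sum())
        den += float((msp + (n_c - 1.0) * msg).sum())
    if den == 0.0:
        return nan
    return num / den


def gst(counts, weight_by_size: bool = False) -> tuple[float, float, float]:
    """Nei's GST = (HT - HS)/HT with HS, HT from the count matrix.

    Returns (GST, HS, HT); NaN GST when HT = 0.  ``weight_by_size``
    switches HS and the pooled frequencies from unweighted deme means to
    sample-size-weighted ones.
    """
    c = _validated_counts(counts)
    n_i = c.sum(axis=1)
    p = c / n_i[:, None]
    he_i = 1.0 - (p**2).sum(axis=1)
    if weight_by_size:
        w = n_i / n_i.sum()
        hs = float(w @ he_i)
        pbar = w @ p
    else:
        hs = float(he_i.mean())
        pbar = p.mean(axis=0)
    ht = float(1.0 - (pbar**2).sum())
    if ht == 0.0:
        return nan, hs, ht
    return (ht - hs) / ht, hs, ht


def gst_prime(counts, weight_by_size: bool = False) -> float:
    """Hedrick's G'ST = GST (k-1+HS) / ((k-1)(1-HS)), NaN when undefined.

    Equals 1 when demes are fixed for disjoint alleles regardless of
    within-deme diversity; never exceeds 1.
    """
    c = _validated_counts(counts)
    g, hs, _ht = gst(c, weight_by_size=weight_by_size)
    if isnan(g):
        return nan
    if hs == 1.0:
        return nan
    k = c.shape[0]
    return float(g * (k - 1.0 + hs) / ((k - 1.0) * (1.0 - hs)))


def rarefied_allelic_richness(counts: Sequence[int], g: int) -> float:
    """Expected distinct alleles in a hypergeometric subsample of g copies:
    E[A_g] = sum_i [1 - C(N - N_i, g) / C(N, g)]."""
    counts = [int(c) for c in counts if c > 0]
    n_tot = sum(counts)
    if not 1 <= g <= n_tot:
        raise ParameterError(f"rarefaction size g={g} outside [1, {n_tot}]")
    denom = comb(n_tot, g)
    return float(sum(1.0 - comb(n_tot - ni, g) / denom for ni in counts))


def drop_inbred_alleles(
    table: GenotypeTable, rng: np.random.Generator
) -> GenotypeTable:
    """One allele-drop replicate: every heterozygous genotype of an
    inbred-flagged individual keeps a single uniformly chosen allele;
    homozygotes and non-inbred individuals are untouched."""
    new_rows: list[list[tuple[int, ...] | None]] = []
    for ind, row in zip(table.individuals, table.genotypes):
        if not ind.inbred:
            new_rows.append(list(row))
            continue
        new_row: list[tuple[int, ...] | None] = []
        for geno in row:
            if geno is None or len(geno) == 1 or geno[0] == geno[1]:
                new_row.append(geno)
            else:
                new_row.append((geno[int(rng.integers(2))],))
        new_rows.append(new_row)
    return table.with_genotypes(new_rows)


def _mean_he(table: GenotypeTable) -> float:
    """Mean over loci of the unweighted across-species mean within-species
    He (monomorphic loci included with He=0)."""
    species = table.species_list()
    vals = []
    for li in range(table.n_loci):
        grouped = table.species_allele_counts(li)
        he_sp = []
        for sp in species:
            counts = grouped.get(sp)
            if not counts:
                continue
            tot = sum(counts.values())
            he_sp.append(1.0 - sum((c / tot) ** 2 for c in counts.values()))
        if he_sp:
            vals.append(float(np.mean(he_sp)))
    if not vals:
        return nan
    return float(np.mean(vals))


def _species_fst(table: GenotypeTable) -> float:
    species = table.species_list()
    per_locus = []
    for li in range(table.n_loci):
        mat, _ = counts_matrix(table.species_allele_counts(li), groups=species)
        if (mat.sum(axis=1) >= 2).all():
            per_locus.append(mat)
    return fst_wc_multilocus(per_locus)


STATISTICS: dict[str, Callable[[GenotypeTable], float]] = {
    "mean_he": _mean_he,
    "multilocus_fst": _species_fst,
}


def inbred_drop_mean(
    table: GenotypeTable,
    statistic: str | Callable[[GenotypeTable], float],
    replicates: int = 200,
    rng: np.random.Generator | None = None,
) -> float:
    """Mean of a table statistic over allele-drop replicate data sets.

    ``statistic`` is a callable on GenotypeTable or one of the registered
    names ("mean_he", "multilocus_fst").  Replicates on which the statistic
    is undefined (NaN) are skipped; more than 10% skipped is an error.
    """
    if replicates < 1:
        raise ParameterError(f"replicates must be >= 1, got {replicates}")
    stat = STATISTICS[statistic] if isinstance(statistic, str) else statistic
    rng = np.random.default_rng() if rng is None else rng
    vals = []
    skipped = 0
    for _ in range(replicates):
        v = stat(drop_inbred_alleles(table, rng))
        if isnan(v):
            skipped += 1
        else:
            vals.append(v)
    if skipped > 0.1 * replicates:
        raise StatisticError(
            f"statistic undefined on {skipped}/{replicates} drop replicates"
        )
    return float(np.mean(vals))


def per_locus_stats(table: GenotypeTable) -> list[LocusStat]:
    """Per-locus He (mean within-species), W&C FST and G'ST between the
    table's two species, plus the pooled allele count."""
    species = table.species_list()
    if len(species) != 2:
        raise ParameterError(f"expected exactly 2 species, got {species}")
    out = []
    for li, locus in enumerate(table.loci):
        grouped = table.species_allele_counts(li)
        mat, alleles = counts_matrix(grouped, groups=species)
        tot = mat.sum(axis=0)
        he_sp = []
        for row in mat:
            n = row.sum()
            if n > 0:
                he_sp.append(1.0 - float(((row / n) ** 2).sum()))
        out.append(
            LocusStat(
                name=locus.name,
                chromosome=locus.chromosome,
                He=float(np.mean(he_sp)) if he_sp else nan,
                fst=fst_wc(mat) if (mat.sum(axis=1) >= 2).all() else nan,
                gst_prime=gst_prime(mat) if (mat.sum(axis=1) >= 2).all() else nan,
                allele_count=int((tot > 0).sum()),
            )
        )
    return out


def dps_distance_matrix(
    table: GenotypeTable,
    grouping: Mapping[str, str] | Callable[[Individual], str],
) -> tuple[list[str], np.ndarray]:
    """Proportion-of-shared-alleles distance between pooled groups:
    D = 1 - (1/L) sum_loci sum_alleles min(p|g1, p|g2).

    ``grouping`` maps individual id -> group (or is a callable on the
    Individual, e.g. ``lambda ind: ind.collection``).  Loci with no data
    in either group of a pair are excluded pairwise.
    """
    group_of = grouping if callable(grouping) else (
        lambda ind: grouping[ind.id]  # type: ignore[index]
    )
    groups: list[str] = []
    for ind in table.individuals:
        g = group_of(ind)
        if g not in groups:
            groups.append(g)
    if len(groups) < 2:
        raise ParameterError("dps distance needs >= 2 groups")
    # per-locus per-group frequency dicts
    freqs: list[dict[str, dict[int, float]]] = []
    for li in range(table.n_loci):
        grouped = table.allele_counts(li, group_of)
        fl: dict[str, dict[int, float]] = {}
        for g, counts in grouped.items():
            tot = sum(counts.values())
            fl[g] = {a: c / tot for a, c in counts.items()}
        freqs.append(fl)
    for g in groups:
        if not any(g in fl for fl in freqs):
            raise StatisticError(f"group {g!r} has no genotype data at any locus")
    k = len(groups)
    dmat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            shared = 0.0
            n_loci = 0
            for fl in freqs:
                fi, fj = fl.get(groups[i]), fl.get(groups[j])
                if fi is None or fj is None:
                    continue
                n_loci += 1
                shared += sum(min(p, fj.get(a, 0.0)) for a, p in fi.items())
            if n_loci == 0:
                raise StatisticError(
                    f"groups {groups[i]!r} and {groups[j]!r} share no typed loci"
                )
            dmat[i, j] = dmat[j, i] = 1.0 - shared / n_loci
    return groups, dmat


def nj_tree(dmat: np.ndarray, labels: Sequence[str]) -> TreeNode:
    """Saitou-Nei neighbour joining on a symmetric zero-diagonal distance
    matrix (>= 3 taxa); returns an (arbitrarily rooted) scikit-bio tree."""
    if len(labels) < 3:
        raise SampleSizeError("neighbour joining needs >= 3 taxa")
    return _skbio_nj(DistanceMatrix(dmat, ids=list(labels)))


def tree_bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions of the taxon set, each encoded as the
    frozenset of its two sides (rooting-independent)."""
    taxa = frozenset(t.name for t in tree.tips())
    parts: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 2 <= len(side) <= len(taxa) - 2:
            parts.add(frozenset((side, taxa - side)))
    return parts


def bootstrap_support(
    table: GenotypeTable,
    grouping: Mapping[str, str] | Callable[[Individual], str],
    replicates: int = 100,
    rng: np.random.Generator | None = None,
) -> tuple[TreeNode, dict[frozenset, float]]:
    """NJ tree on the Dps distance with locus-bootstrap node support.

    Loci are resampled with replacement ``replicates`` times; support for
    each bipartition of the point-estimate tree is the percentage of
    replicate trees containing it.
    """
    rng = np.random.default_rng() if rng is None else rng
    labels, dmat = dps_distance_matrix(table, grouping)
    tree = nj_tree(dmat, labels)
    parts = tree_bipartitions(tree)
    hits = {p: 0 for p in parts}
    n_loci = table.n_loci
    for _ in range(replicates):
        idx = rng.integers(0, n_loci, size=n_loci)
        bt = table.subset_loci(idx)
        blabels, bdmat = dps_distance_matrix(bt, grouping)
        bparts = tree_bipartitions(nj_tree(bdmat, blabels))
        for p in parts:
            if p in bparts:
                hits[p] += 1
    support = {p: 100.0 * h / replicates for p, h in hits.items()}
    return tree, support
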