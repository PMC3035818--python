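"""Diploid microsatellite genotype tables and their CSV dialect.

A table holds individuals (with species, collection and inbred flags),
loci (with chromosome labels X/2/3/4) and per-individual-per-locus
genotypes.  A genotype is a tuple of allele sizes: length 2 for an intact
diploid call, length 1 after the inbred allele-drop reduction, or ``None``
when missing.

On disk the table is a wide CSV — columns id,species,collection,inbred and
one ``<locus>.1``/``<locus>.2`` pair per locus, missing alleles empty —
plus a sidecar ``<file>.loci.tsv`` carrying the locus -> chromosome map,
which the wide header cannot hold.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping

import numpy as np

from .exceptions import MetadataError, ParameterError

__all__ = [
    "Individual",
    "Locus",
    "GenotypeTable",
    "read_genotype_table",
    "write_genotype_table",
]

CHROMOSOMES = ("X", "2", "3", "4")

Genotype = "tuple[int, ...] | None"


@dataclass(frozen=True)
class Individual:
    id: str
    species: str
    collection: str
    inbred: bool


@dataclass(frozen=True)
class Locus:
    name: str
    chromosome: str

    def __post_init__(self) -> None:
        if self.chromosome not in CHROMOSOMES:
            raise ParameterError(
                f"chromosome label must be one of {CHROMOSOMES}, "
                f"got {self.chromosome!r} for locus {self.name!r}"
            )


@dataclass
class GenotypeTable:
    """individuals x loci allele-size table.

    ``genotypes[i][l]`` is the genotype of individual ``i`` at locus
    ``l``: a 2-tuple (order-free), a 1-tuple for a reduced inbred call,
    or None if missing.
    """

    individuals: list[Individual]
    loci: list[Locus]
    genotypes: list[list[tuple[int, ...] | None]]

    def __post_init__(self) -> None:
        if len(self.genotypes) != len(self.individuals):
            raise ParameterError("one genotype row per individual required")
        for row in self.genotypes:
            if len(row) != len(self.loci):
                raise ParameterError("one genotype per locus required")
            for g in row:
                if g is not None and len(g) not in (1, 2):
                    raise ParameterError(f"genotype must have 1 or 2 alleles, got {g}")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def species_list(self) -> list[str]:
        seen: list[str] = []
        for ind in self.individuals:
            if ind.species not in seen:
                seen.append(ind.species)
        return seen

    def allele_counts(
        self, locus_index: int, group_of: Callable[[Individual], str]
    ) -> dict[str, dict[int, int]]:
        """Allele-copy counts at one locus, keyed by group label."""
        out: dict[str, dict[int, int]] = {}
        for ind, row in zip(self.individuals, self.genotypes):
            g = row[locus_index]
            if g is None:
                continue
            counts = out.setdefault(group_of(ind), {})
            for a in g:
                counts[a] = counts.get(a, 0) + 1
        return out

    def species_allele_counts(self, locus_index: int) -> dict[str, dict[int, int]]:
        return self.allele_counts(locus_index, lambda ind: ind.species)

    def subset_loci(self, indices: Iterable[int]) -> "GenotypeTable":
        idx = list(indices)
        return GenotypeTable(
            individuals=self.individuals,
            loci=[self.loci[i] for i in idx],
            genotypes=[[row[i] for i in idx] for row in self.genotypes],
        )

    def with_genotypes(
        self, genotypes: list[list[tuple[int, ...] | None]]
    ) -> "GenotypeTable":
        return GenotypeTable(
            individuals=self.individuals, loci=self.loci, genotypes=genotypes
        )


def counts_matrix(
    grouped: Mapping[str, Mapping[int, int]], groups: list[str] | None = None
) -> tuple[np.ndarray, list[int]]:
    """Stack per-group allele-count dicts into a (group x allele) matrix
    over the union of observed alleles (sorted)."""
    if groups is None:
        groups = sorted(grouped)
    alleles = sorted({a for g in groups for a in grouped.get(g, {})})
    mat = np.zeros((len(groups), len(alleles)), dtype=np.int64)
    for gi, g in enumerate(groups):
        for ai, a in enumerate(alleles):
            mat[gi, ai] = grouped.get(g, {}).get(a, 0)
    return mat, alleles


def _loci_sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".loci.tsv")


def write_genotype_table(
    table: GenotypeTable, path: str | Path, loci_path: str | Path | None = None
) -> None:
    """Write the wide CSV and its loci sidecar (deterministic byte output)."""
    path = Path(path)
    loci_path = _loci_sidecar(path) if loci_path is None else Path(loci_path)
    header = ["id", "species", "collection", "inbred"]
    for locus in table.loci:
        header += [f"{locus.name}.1", f"{locus.name}.2"]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(header)
        for ind, row in zip(table.individuals, table.genotypes):
            cells = [ind.id, ind.species, ind.collection, int(ind.inbred)]
            for g in row:
                if g is None:
                    cells += ["", ""]
                elif len(g) == 1:
                    cells += [g[0], ""]
                else:
                    cells += [g[0], g[1]]
            w.writerow(cells)
    with open(loci_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["name", "chromosome"])
        for locus in table.loci:
            w.writerow([locus.name, locus.chromosome])


def read_genotype_table(
    path: str | Path, loci_path: str | Path | None = None
) -> GenotypeTable:
    """Read the wide CSV dialect written by :func:`write_genotype_table`."""
    path = Path(path)
    loci_path = _loci_sidecar(path) if loci_path is None else Path(loci_path)
    if not loci_path.exists():
        raise MetadataError(
            f"loci sidecar {loci_path} not found; chromosome labels are required"
        )
    chrom: dict[str, str] = {}
    order: list[str] = []
    with open(loci_path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            chrom[row["name"]] = row["chromosome"]
            order.append(row["name"])
    individuals: list[Individual] = []
    genotypes: list[list[tuple[int, ...] | None]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        loci_names = [h[:-2] for h in header[4:]][::2]
        if loci_names != order:
            raise MetadataError(
                "loci sidecar order does not match genotype CSV columns"
            )
        for cells in reader:
            individuals.append(
                Individual(
                    id=cells[0],
                    species=cells[1],
                    collection=cells[2],
                    inbred=bool(int(cells[3])),
                )
            )
            row: list[tuple[int, ...] | None] = []
            for li in range(len(loci_names)):
                a, b = cells[4 + 2 * li], cells[5 + 2 * li]
                if a == "" and b == "":
                    row.append(None)
                elif b == "":
                    row.append((int(a),))
                else:
                    row.append((int(a), int(b)))
            genotypes.append(row)
    loci = [Locus(name=n, chromosome=chrom[n]) for n in loci_names]
    return GenotypeTable(individuals=individuals, loci=loci, genotypes=genotypes)
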