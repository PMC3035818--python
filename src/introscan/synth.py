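"""Study-shaped synthetic data: microsatellite genotype tables and mtDNA
haplotype-class alignments.

The defaults emulate the study design: 125 *D. mauritiana* lines (mostly
inbred isofemale lines) and 15 *D. simulans* individuals typed at 25
microsatellites spread over the X, 2nd, 3rd and 4th chromosomes (the
single 4th-chromosome locus fixed for the same allele in both species),
plus mtDNA haplotype classes maI-maIII / siI-siIII with controlled
pairwise silent-substitution counts — in particular an introgressed
recipient class planted exactly 3 silent substitutions from its nearest
donor class over a 737-site silent mask.

Microsatellite introgression is modelled by deme-swapped lineage sampling:
introgressed loci are simulated with the split time collapsed to zero, so
their reduced differentiation arises from a genuine shared genealogy
rather than post-hoc allele copying.  Sequence classes are planted
deterministically on a star-like scaffold (each class derives from its
donor by substitutions at fresh silent sites), so substitution counts are
exact by construction — which is what the dating stage needs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignment import Alignment, SequenceRecord
from .coalescent import IsolationModel, drop_mutations, simulate_genealogy
from .exceptions import ParameterError
from .genotypes import GenotypeTable, Individual, Locus
from .microsat import assign_steps, haplotypes_to_alleles

__all__ = [
    "HaplogroupSpec",
    "SynthSpec",
    "gen_genotype_table",
    "gen_alignment",
    "write_alignment_files",
]

_MAU_COLLECTIONS = ("RB", "RED", "CS", "G", "MS", "MAU")


@dataclass(frozen=True)
class HaplogroupSpec:
    """One haplotype class: planted ``substitutions`` silent-site changes
    from its ``donor`` class (None = the scaffold root class)."""

    label: str
    species: str
    count: int
    substitutions: int = 0
    donor: str | None = None


def _default_plan() -> tuple[HaplogroupSpec, ...]:
    # siII is the scaffold root; maI is identical to siIII (the long-known
    # shared haplogroup); maIII sits 3 silent substitutions from siII.
    return (
        HaplogroupSpec("siII", "simulans", 10, 0, None),
        HaplogroupSpec("siI", "simulans", 2, 30, "siII"),
        HaplogroupSpec("siIII", "simulans", 3, 35, "siII"),
        HaplogroupSpec("maI", "mauritiana", 102, 0, "siIII"),
        HaplogroupSpec("maII", "mauritiana", 19, 40, "siII"),
        HaplogroupSpec("maIII", "mauritiana", 4, 3, "siII"),
    )


@dataclass(frozen=True)
class SynthSpec:
    """Synthetic study design; defaults reproduce the study conditions."""

    n_mau: int = 125
    n_sim: int = 15
    n_loci: int = 25
    split_tau: float = 1.25
    theta: float = 4.0
    inbred_fraction: float = 0.8
    n_introgressed_loci: int = 5
    haplogroup_plan: tuple[HaplogroupSpec, ...] = field(
        default_factory=_default_plan
    )
    silent_sites: int = 737
    seq_length: int = 2088
    mu: float = 1.6e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_mau, self.n_sim, self.n_loci) <= 0:
            raise ParameterError("n_mau, n_sim and n_loci must be positive")
        if not 0.0 <= self.inbred_fraction <= 1.0:
            raise ParameterError("inbred_fraction must be in [0, 1]")
        if not 0 <= self.n_introgressed_loci <= self.n_loci:
            raise ParameterError("n_introgressed_loci must be <= n_loci")
        if self.silent_sites > self.seq_length:
            raise ParameterError("silent_sites cannot exceed seq_length")
        budget = sum(h.substitutions for h in self.haplogroup_plan)
        if budget > self.silent_sites:
            raise ParameterError(
                f"planted substitutions ({budget}) exceed the "
                f"{self.silent_sites}-site silent budget"
            )
        labels = [h.label for h in self.haplogroup_plan]
        if len(set(labels)) != len(labels):
            raise ParameterError("duplicate haplogroup labels in plan")
        for h in self.haplogroup_plan:
            if h.donor is not None and h.donor not in labels[: labels.index(h.label)]:
                raise ParameterError(
                    f"haplogroup {h.label!r} names donor {h.donor!r} "
                    "not defined earlier in the plan"
                )


def _chromosome_labels(n_loci: int) -> list[str]:
    """Cycle loci over X/2/3 with the last locus on the 4th chromosome."""
    labels = [("X", "2", "3")[i % 3] for i in range(n_loci - 1)]
    labels.append("4")
    return labels


def gen_genotype_table(spec: SynthSpec, rng: np.random.Generator) -> GenotypeTable:
    """Simulate the diploid microsatellite table.

    Neutral loci follow the isolation model at ``split_tau``; introgressed
    loci are drawn with the recipient deme's lineages sharing the donor
    pool (tau = 0); the 4th-chromosome locus is forced monomorphic.
    Consecutive simulated chromosomes are paired into diploids.
    """
    chroms = _chromosome_labels(spec.n_loci)
    autosomal = [i for i, c in enumerate(chroms) if c != "4"]
    intro = set(
        rng.choice(autosomal, size=spec.n_introgressed_loci, replace=False).tolist()
        if spec.n_introgressed_loci
        else []
    )
    n1, n2 = 2 * spec.n_mau, 2 * spec.n_sim
    baseline = 100
    allele_cols: list[np.ndarray] = []
    for li in range(spec.n_loci):
        if chroms[li] == "4":
            allele_cols.append(np.full(n1 + n2, baseline, dtype=np.int64))
            continue
        tau = 0.0 if li in intro else spec.split_tau
        model = IsolationModel(n1=n1, n2=n2, theta=spec.theta, tau=tau)
        tree = simulate_genealogy(model, rng)
        locus = drop_mutations(tree, spec.theta, rng)
        steps = assign_steps(locus.site_count, rng)
        allele_cols.append(
            haplotypes_to_alleles(locus, steps, baseline=baseline).alleles
        )
    individuals = []
    genotypes: list[list[tuple[int, ...] | None]] = []
    inbred_flags = rng.random(spec.n_mau) < spec.inbred_fraction
    for i in range(spec.n_mau):
        individuals.append(
            Individual(
                id=f"MAU{i + 1:03d}",
                species="mauritiana",
                collection=_MAU_COLLECTIONS[i % len(_MAU_COLLECTIONS)],
                inbred=bool(inbred_flags[i]),
            )
        )
        genotypes.append(
            [(int(col[2 * i]), int(col[2 * i + 1])) for col in allele_cols]
        )
    for j in range(spec.n_sim):
        individuals.append(
            Individual(
                id=f"SIM{j + 1:02d}",
                species="simulans",
                collection="SIM",
                inbred=False,
            )
        )
        genotypes.append(
            [
                (int(col[n1 + 2 * j]), int(col[n1 + 2 * j + 1]))
                for col in allele_cols
            ]
        )
    loci = [
        Locus(name=f"ms{i + 1:02d}", chromosome=chroms[i])
        for i in range(spec.n_loci)
    ]
    return GenotypeTable(individuals=individuals, loci=loci, genotypes=genotypes)


def gen_alignment(spec: SynthSpec, rng: np.random.Generator) -> Alignment:
    """Build the mtDNA haplotype-class alignment with its silent-site mask.

    Classes are planted on a star-like scaffold: each class copies its
    donor's sequence and mutates the requested number of fresh silent
    sites, so pairwise class distances are exact path sums.  Sequences
    within a class are identical; the ``collection`` label of each record
    carries its haplotype-class name.
    """
    mask = np.sort(rng.choice(spec.seq_length, size=spec.silent_sites, replace=False))
    bases = np.array(list("ACGT"))
    root = bases[rng.integers(0, 4, size=spec.seq_length)]
    fresh = list(map(int, mask))  # silent columns not yet used by any class
    class_seq: dict[str, np.ndarray] = {}
    for h in spec.haplogroup_plan:
        parent = root if h.donor is None else class_seq[h.donor]
        seq = parent.copy()
        for _ in range(h.substitutions):
            col = fresh.pop(int(rng.integers(len(fresh))))
            alt = [b for b in "ACGT" if b != seq[col]]
            seq[col] = alt[int(rng.integers(3))]
        class_seq[h.label] = seq
    records = []
    for h in spec.haplogroup_plan:
        residues = "".join(class_seq[h.label])
        for i in range(h.count):
            records.append(
                SequenceRecord(
                    id=f"{h.label}_{i + 1:03d}",
                    species=h.species,
                    collection=h.label,
                    residues=residues,
                )
            )
    return Alignment(records=records, site_mask=frozenset(map(int, mask)))


def write_alignment_files(
    aln: Alignment, fasta_path: str | Path, meta_path: str | Path,
    mask_path: str | Path,
) -> None:
    """Write FASTA + id,species,collection CSV + one-index-per-line mask,
    with deterministic byte output."""
    with open(fasta_path, "w") as fh:
        for rec in aln.records:
            fh.write(f">{rec.id}\n{rec.residues}\n")
    with open(meta_path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["id", "species", "collection"])
        for rec in aln.records:
            w.writerow([rec.id, rec.species, rec.collection])
    with open(mask_path, "w") as fh:
        for idx in sorted(aln.site_mask or ()):
            fh.write(f"{idx}\n")
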