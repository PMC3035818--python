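"""Labelled sequence alignments and DnaSP-style diversity summaries.

The container couples a FASTA alignment with per-sequence species and
collection labels and an optional set of "silent site" columns.  Any
column containing an alignment gap ('-') or an ambiguous base ('N') in any
sequence is excluded from every statistic — sample sizes and site counts
therefore refer to the analysed (gap-free) columns, the same convention as
reporting sequence length "after discarding alignment gaps".

Statistics follow the standard definitions: S counts columns with at least
two resolved bases; haplotypes are distinct strings over analysed columns;
haplotype diversity Hd = n(1 - sum p_i^2)/(n - 1); nucleotide diversity is
the mean pairwise proportion of differing analysed sites, optionally
Jukes-Cantor corrected as -(3/4) ln(1 - (4/3) p).
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from math import log
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table

from .exceptions import (
    AlignmentError,
    FrameError,
    JCDomainError,
    MetadataError,
    SampleSizeError,
)

__all__ = [
    "SequenceRecord",
    "Alignment",
    "DiversitySummary",
    "BetweenSpeciesSummary",
    "read_alignment",
    "read_metadata",
    "read_site_mask",
    "write_site_mask",
    "diversity_summary",
    "between_species_summary",
    "silent_site_mask",
    "jukes_cantor",
]

_VALID = frozenset("ACGTN-")


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    species: str
    collection: str
    residues: str


class BetweenSpeciesSummary(NamedTuple):
    """Fixed differences F, shared polymorphisms S*, and JC-corrected mean
    pairwise silent divergence Ks between two species."""

    F: int
    S_star: int
    Ks: float


@dataclass
class Alignment:
    """Equal-length labelled sequences plus an optional silent-site mask."""

    records: list[SequenceRecord]
    site_mask: frozenset[int] | None = None
    _matrix: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("alignment has no sequences")
        length = len(self.records[0].residues)
        for rec in self.records:
            if len(rec.residues) != length:
                raise AlignmentError(
                    f"sequence {rec.id!r} has length {len(rec.residues)}, "
                    f"expected {length}"
                )
            bad = set(rec.residues) - _VALID
            if bad:
                raise AlignmentError(
                    f"sequence {rec.id!r} contains invalid residues {sorted(bad)}"
                )
        if self.site_mask is not None:
            self.site_mask = frozenset(self.site_mask)
            if self.site_mask and (
                min(self.site_mask) < 0 or max(self.site_mask) >= length
            ):
                raise AlignmentError("site_mask index outside alignment columns")

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def length(self) -> int:
        return len(self.records[0].residues)

    @property
    def matrix(self) -> np.ndarray:
        """(n x length) array of single characters."""
        if self._matrix is None:
            self._matrix = np.array(
                [list(rec.residues) for rec in self.records], dtype="<U1"
            )
        return self._matrix

    def excluded_columns(self) -> np.ndarray:
        """Columns containing '-' or 'N' in any sequence (recorded, not
        silently dropped)."""
        m = self.matrix
        return np.flatnonzero(((m == "-") | (m == "N")).any(axis=0))

    def analysed_columns(self, mask_only: bool = False) -> np.ndarray:
        """Gap/N-free column indices; intersected with the silent-site mask
        when ``mask_only``."""
        m = self.matrix
        keep = ~((m == "-") | (m == "N")).any(axis=0)
        if mask_only:
            if self.site_mask is None:
                raise AlignmentError("mask_only requested but site_mask is absent")
            sel = np.zeros(self.length, dtype=bool)
            sel[list(self.site_mask)] = True
            keep &= sel
        return np.flatnonzero(keep)

    @property
    def analysed_sites(self) -> int:
        return len(self.analysed_columns())

    def species_set(self) -> set[str]:
        return {rec.species for rec in self.records}

    def subset(self, ids: Iterable[str]) -> "Alignment":
        """Alignment restricted to the given sequence ids (mask retained)."""
        wanted = set(ids)
        recs = [rec for rec in self.records if rec.id in wanted]
        missing = wanted - {rec.id for rec in recs}
        if missing:
            raise MetadataError(f"ids not in alignment: {sorted(missing)}")
        return Alignment(records=recs, site_mask=self.site_mask)

    def subset_species(self, species: str) -> "Alignment":
        recs = [rec for rec in self.records if rec.species == species]
        if not recs:
            raise SampleSizeError(f"no sequences for species {species!r}")
        return Alignment(records=recs, site_mask=self.site_mask)


@dataclass(frozen=True)
class DiversitySummary:
    """Per-sample diversity: n, segregating sites S, haplotype count h,
    haplotype diversity Hd, and per-site nucleotide diversity (raw and
    Jukes-Cantor corrected) over ``analysed_sites`` columns."""

    n: int
    S: int
    h: int
    Hd: float
    pi_raw: float
    pi_jc: float
    analysed_sites: int


def read_metadata(path: str | Path) -> dict[str, dict[str, str]]:
    """Read an id,species,collection CSV/TSV into a metadata map."""
    path = Path(path)
    delim = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    out: dict[str, dict[str, str]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter=delim):
            out[row["id"]] = {
                "species": row["species"],
                "collection": row.get("collection", ""),
            }
    return out


def read_alignment(
    path: str | Path,
    labels: Mapping[str, Mapping[str, str]] | str | Path,
    site_mask: Iterable[int] | None = None,
) -> Alignment:
    """Load a FASTA alignment with per-id species/collection labels.

    ``labels`` is either a mapping id -> {species, collection} or the path
    of a CSV/TSV with columns id,species,collection.  Every record id must
    have a metadata entry.
    """
    if isinstance(labels, (str, Path)):
        labels = read_metadata(labels)
    records = []
    for seq in SeqIO.parse(str(path), "fasta"):
        meta = labels.get(seq.id)
        if meta is None:
            raise MetadataError(f"no metadata for sequence id {seq.id!r}")
        records.append(
            SequenceRecord(
                id=seq.id,
                species=meta["species"],
                collection=meta.get("collection", ""),
                residues=str(seq.seq).upper(),
            )
        )
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    return Alignment(
        records=records,
        site_mask=frozenset(site_mask) if site_mask is not None else None,
    )


def read_site_mask(path: str | Path) -> frozenset[int]:
    """Read a site mask: one 0-based column index per line."""
    with open(path) as fh:
        return frozenset(int(line) for line in fh if line.strip())


def write_site_mask(mask: Iterable[int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for idx in sorted(mask):
            fh.write(f"{idx}\n")


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor distance -(3/4) ln(1 - (4/3) p) for a p-distance."""
    if p < 0:
        raise ValueError(f"p-distance must be nonnegative, got {p}")
    if p == 0:
        return 0.0
    if p >= 0.75:
        raise JCDomainError(f"p-distance {p} >= 3/4: JC correction undefined")
    return -0.75 * log(1.0 - p * 4.0 / 3.0)


def _pairwise_mean_pdist(sub: np.ndarray) -> float:
    """Mean over all C(n,2) pairs of the per-pair proportion of differing
    columns of an (n x m) character submatrix."""
    n, m = sub.shape
    total = 0
    for i in range(n - 1):
        total += (sub[i + 1 :] != sub[i]).sum()
    n_pairs = n * (n - 1) // 2
    return total / (n_pairs * m)


def diversity_summary(aln: Alignment, mask_only: bool = False) -> DiversitySummary:
    """Compute S, h, Hd and nucleotide diversity over analysed columns.

    With ``mask_only`` the statistics are restricted to silent sites
    (requires the alignment to carry a site mask).
    """
    n = aln.n
    if n < 2:
        raise SampleSizeError(f"diversity summary needs n >= 2, got {n}")
    cols = aln.analysed_columns(mask_only=mask_only)
    if len(cols) == 0:
        raise AlignmentError("no analysed columns remain after exclusions")
    sub = aln.matrix[:, cols]
    s_count = int(
        sum(1 for j in range(sub.shape[1]) if len(set(sub[:, j])) > 1)
    )
    haplos = Counter("".join(row) for row in sub)
    h = len(haplos)
    freqs = np.array(list(haplos.values())) / n
    hd = 0.0 if h == 1 else n * (1.0 - float(np.sum(freqs**2))) / (n - 1)
    pi_raw = _pairwise_mean_pdist(sub)
    return DiversitySummary(
        n=n,
        S=s_count,
        h=h,
        Hd=hd,
        pi_raw=pi_raw,
        pi_jc=jukes_cantor(pi_raw),
        analysed_sites=len(cols),
    )


def between_species_summary(
    aln: Alignment, species_a: str, species_b: str
) -> BetweenSpeciesSummary:
    """Fixed differences, shared polymorphisms and silent divergence Ks.

    F counts analysed columns where the two species share no base; S*
    counts columns polymorphic within both species with >= 2 bases in
    common.  Ks is the Jukes-Cantor correction of the mean between-species
    pairwise p-distance, over the silent-site mask when one is present.
    """
    rows_a = [i for i, r in enumerate(aln.records) if r.species == species_a]
    rows_b = [i for i, r in enumerate(aln.records) if r.species == species_b]
    if not rows_a or not rows_b:
        raise SampleSizeError(
            f"both species need >= 1 sequence ({species_a!r}: {len(rows_a)}, "
            f"{species_b!r}: {len(rows_b)})"
        )
    cols = aln.analysed_columns()
    m = aln.matrix
    f_count = 0
    s_star = 0
    for j in cols:
        set_a = set(m[rows_a, j])
        set_b = set(m[rows_b, j])
        if not (set_a & set_b):
            f_count += 1
        elif len(set_a) >= 2 and len(set_b) >= 2 and len(set_a & set_b) >= 2:
            s_star += 1
    ks_cols = aln.analysed_columns(mask_only=aln.site_mask is not None)
    sub = m[:, ks_cols]
    total = 0
    for i in rows_a:
        for j in rows_b:
            total += int((sub[i] != sub[j]).sum())
    p_mean = total / (len(rows_a) * len(rows_b) * len(ks_cols))
    return BetweenSpeciesSummary(F=f_count, S_star=s_star, Ks=jukes_cantor(p_mean))


def _third_position_degeneracy(codon: str) -> int:
    """Number of third-position bases preserving the encoded amino acid
    (stop codons are treated as their own translation class)."""
    fwd = standard_dna_table.forward_table
    stops = set(standard_dna_table.stop_codons)
    aa = "*" if codon in stops else fwd[codon]
    count = 0
    for b in "ACGT":
        var = codon[:2] + b
        var_aa = "*" if var in stops else fwd[var]
        if var_aa == aa:
            count += 1
    return count


def silent_site_mask(aln: Alignment, frame_offset: int = 0) -> frozenset[int]:
    """Heuristic silent-site classifier for coding alignments.

    Returns the third-codon-position columns whose observed codons are all
    at least two-fold degenerate under the standard genetic code.  This is
    a helper: callers with a curated silent-site annotation should supply
    their own mask.
    """
    if frame_offset < 0 or aln.length < frame_offset + 3:
        raise FrameError(
            f"frame_offset {frame_offset} leaves no complete codon in a "
            f"length-{aln.length} alignment"
        )
    stops = set(standard_dna_table.stop_codons)
    mask: set[int] = set()
    n_codons = (aln.length - frame_offset) // 3
    for c in range(n_codons):
        start = frame_offset + 3 * c
        codons = []
        for rec in aln.records:
            codon = rec.residues[start : start + 3]
            if set(codon) <= set("ACGT"):
                codons.append(codon)
        if not codons:
            continue
        if c < n_codons - 1 and all(cd in stops for cd in codons):
            raise FrameError(
                f"internal stop codon in all sequences at codon {c} "
                f"(columns {start}-{start + 2}); check the reading frame"
            )
        if all(_third_position_degeneracy(cd) >= 2 for cd in codons):
            mask.add(start + 2)
    return frozenset(mask)


def summaries_table(
    aln: Alignment, groups: Mapping[str, Sequence[str]], mask_only: bool = False
) -> list[dict]:
    """Tabulate diversity summaries for named sequence groups, one row per
    group in n,S,h,Hd,pi column order."""
    rows = []
    for name, ids in groups.items():
        d = diversity_summary(aln.subset(ids), mask_only=mask_only)
        rows.append(
            {
                "group": name,
                "n": d.n,
                "S": d.S,
                "h": d.h,
                "Hd": round(d.Hd, 2),
                "pi": round(d.pi_jc, 5),
            }
        )
    return rows
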