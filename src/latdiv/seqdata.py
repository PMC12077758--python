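"""Georeferenced sequence input, alignment-site filtering, haplotype collapsing.

Sequences arrive as per-species aligned FASTA plus a metadata table keyed by
accession (species/lineage label, signed decimal latitude, longitude).  Before
diversity estimation, alignment columns containing gaps or any non-ACGT symbol
in *any* sequence of a species are removed for *all* sequences of that species
(complete deletion), so the per-site denominator of nucleotide diversity is
unambiguous and band estimates within a species share one site set.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

_VALID_BASES = frozenset("ACGT")
_METADATA_COLUMNS = ("accession", "species_id", "latitude", "longitude")


@dataclass(frozen=True)
class SequenceRecord:
    """One georeferenced COI sequence.

    ``species_id`` is a lineage label: cryptic lineages of a nominal species
    (e.g. northern/southern clades) carry distinct labels and are analysed
    separately throughout.
    """

    accession: str
    species_id: str
    latitude: float
    longitude: float
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"empty sequence for accession {self.accession!r}")
        if not np.isfinite(self.latitude) or not (-90 <= self.latitude <= 90):
            raise ValueError(
                f"latitude {self.latitude!r} out of [-90, 90] for {self.accession!r}"
            )
        if not np.isfinite(self.longitude) or not (-180 <= self.longitude <= 180):
            raise ValueError(
                f"longitude {self.longitude!r} out of [-180, 180] for {self.accession!r}"
            )


@dataclass
class HaplotypeSample:
    """Distinct haplotypes with multiplicities for one (species, band) cell.

    Haplotype strings are over the retained (usable) alignment columns only;
    ``L`` is the number of those columns and is the per-site denominator used
    by the diversity estimators.
    """

    species_id: str
    band: int
    haplotypes: list[str]
    counts: list[int]
    n: int
    L: int

    def __post_init__(self):
        if self.n < 1 or self.L < 1:
            raise ValueError("HaplotypeSample requires n >= 1 and L >= 1")
        if sum(self.counts) != self.n:
            raise ValueError("haplotype counts must sum to n")
        if any(c < 1 for c in self.counts):
            raise ValueError("haplotype counts must be positive")
        if len(set(self.haplotypes)) != len(self.haplotypes):
            raise ValueError("haplotypes must be pairwise distinct")
        if any(len(h) != self.L for h in self.haplotypes):
            raise ValueError("all haplotypes must have length L")

    def expand(self) -> list[str]:
        """Explicit sequence list (haplotypes repeated by their counts)."""
        out: list[str] = []
        for hap, c in zip(self.haplotypes, self.counts):
            out.extend([hap] * c)
        return out


def _open_maybe_gzip(source):
    if hasattr(source, "read"):
        return source
    path = Path(source)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def _read_metadata(source) -> pd.DataFrame:
    meta = pd.read_csv(source, sep=None, engine="python", comment="#",
                       dtype={"accession": str, "species_id": str})
    missing = [c for c in _METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata is missing required columns: {missing}")
    for col in ("latitude", "longitude"):
        vals = pd.to_numeric(meta[col], errors="coerce")
        if vals.isna().any():
            bad = meta.loc[vals.isna(), "accession"].tolist()[:5]
            raise ValueError(f"non-numeric {col} for accession(s) {bad}")
        meta[col] = vals
    if meta["accession"].duplicated().any():
        dup = meta.loc[meta["accession"].duplicated(), "accession"].tolist()[:5]
        raise ValueError(f"duplicate accession(s) in metadata: {dup}")
    return meta


def read_records(fasta_source, metadata_source) -> list[SequenceRecord]:
    """Join FASTA entries to a metadata table into :class:`SequenceRecord` s.

    The join key is the FASTA id up to the first whitespace (GenBank-style
    headers).  Every FASTA entry must resolve to exactly one metadata row;
    within a ``species_id``, all aligned sequences must share one length.
    """
    meta = _read_metadata(metadata_source).set_index("accession")
    records: list[SequenceRecord] = []
    handle = _open_maybe_gzip(fasta_source)
    try:
        for entry in SeqIO.parse(handle, "fasta"):
            acc = entry.id
            if acc not in meta.index:
                raise ValueError(f"FASTA id {acc!r} has no metadata row")
            row = meta.loc[acc]
            records.append(SequenceRecord(
                accession=acc,
                species_id=str(row["species_id"]),
                latitude=float(row["latitude"]),
                longitude=float(row["longitude"]),
                sequence=str(entry.seq).upper(),
            ))
    finally:
        if not hasattr(fasta_source, "read"):
            handle.close()
    if not records:
        raise ValueError("FASTA source contained no sequences")
    seen: set[str] = set()
    for rec in records:
        if rec.accession in seen:
            raise ValueError(f"duplicate FASTA id {rec.accession!r}")
        seen.add(rec.accession)
    lengths: dict[str, int] = {}
    for rec in records:
        length = lengths.setdefault(rec.species_id, len(rec.sequence))
        if len(rec.sequence) != length:
            raise ValueError(
                f"unequal aligned lengths within species {rec.species_id!r}: "
                f"{length} vs {len(rec.sequence)} ({rec.accession!r})"
            )
    return records


def filter_alignment_sites(
    sequences: Sequence[str],
) -> tuple[list[str], int, list[int]]:
    """Complete deletion of unusable alignment columns.

    A column is removed from every sequence if *any* sequence carries a gap
    ``-`` or a symbol outside A/C/G/T (N, IUPAC ambiguity codes, ...) at that
    position.  Returns the filtered sequences, the retained-column count L and
    the 0-based indices of retained columns for audit.
    """
    if not sequences:
        raise ValueError("no sequences to filter")
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
    arr = np.array([list(s.upper()) for s in sequences])
    usable = np.all(np.isin(arr, list(_VALID_BASES)), axis=0)
    kept = np.flatnonzero(usable)
    if kept.size == 0:
        raise ValueError("no usable sites after complete deletion")
    filtered = ["".join(row) for row in arr[:, kept]]
    return filtered, int(kept.size), kept.tolist()


def collapse_haplotypes(
    sequences: Sequence[str], species_id: str, band: int
) -> HaplotypeSample:
    """Collapse site-filtered sequences to distinct haplotypes with counts.

    Haplotype identity is exact string equality on retained columns; ordering
    is first occurrence in the input, so the result is deterministic.
    """
    seqs = list(sequences)
    if not seqs:
        raise ValueError("cannot collapse an empty sequence set")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("sequences must be equal length (site-filtered)")
    counts: dict[str, int] = {}
    for s in seqs:
        counts[s] = counts.get(s, 0) + 1
    return HaplotypeSample(
        species_id=species_id,
        band=int(band),
        haplotypes=list(counts.keys()),
        counts=list(counts.values()),
        n=len(seqs),
        L=lengths.pop(),
    )


def write_haplotype_table(samples: Iterable[HaplotypeSample], path) -> None:
    """Export haplotype frequency tables as TSV."""
    rows = []
    for s in samples:
        for i, (hap, c) in enumerate(zip(s.haplotypes, s.counts)):
            rows.append((s.species_id, s.band, i, c, hap))
    pd.DataFrame(
        rows, columns=["species_id", "band", "haplotype_index", "count", "sequence"]
    ).to_csv(path, sep="\t", index=False)
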