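"""Nei nucleotide diversity (pi) and haplotype diversity (Hd) per band cell.

pi is the average per-site proportion of nucleotide differences between two
sequences drawn at random from the cell; Hd is the probability that two
randomly drawn sequences carry different haplotypes, ignoring how different
they are.  Both use the unbiased n/(n-1) sample correction by default.
Distances are raw per-site difference proportions over the complete-deletion
site set — no substitution-model correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from latdiv.banding import BandCell
from latdiv.seqdata import (
    HaplotypeSample,
    SequenceRecord,
    collapse_haplotypes,
    filter_alignment_sites,
)


@dataclass
class DiversityEstimate:
    species_id: str
    band: int
    n: int
    L: int
    pi: float
    hd: float


def _pairwise_site_diff(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def nucleotide_diversity(sample: HaplotypeSample, unbiased: bool = True) -> float:
    """Average per-site difference proportion between two random sequences.

    Computed from haplotype counts: with c_i copies of haplotype i and d_ij
    the per-site difference proportion, pi = sum_{i<j} c_i c_j d_ij / C(n, 2)
    — identical arithmetic to enumerating all unordered sequence pairs (pairs
    within a haplotype contribute zero).  ``unbiased=False`` divides by n^2
    ordered pairs instead (the plug-in estimator).
    """
    n = sample.n
    if n < 2:
        raise ValueError("nucleotide diversity undefined for n < 2")
    haps = sample.haplotypes
    counts = sample.counts
    total = 0.0
    for i in range(len(haps)):
        for j in range(i + 1, len(haps)):
            d_ij = _pairwise_site_diff(haps[i], haps[j]) / sample.L
            total += counts[i] * counts[j] * d_ij
    if unbiased:
        return total / (n * (n - 1) / 2.0)
    return 2.0 * total / (n * n)


def haplotype_diversity(sample: HaplotypeSample, unbiased: bool = True) -> float:
    """Probability that two randomly drawn sequences are different haplotypes.

    Hd = (n/(n-1)) * (1 - sum_i x_i^2) with x_i = c_i / n; ``unbiased=False``
    omits the n/(n-1) factor.
    """
    n = sample.n
    if n < 2:
        raise ValueError("haplotype diversity undefined for n < 2")
    x = np.asarray(sample.counts, dtype=float) / n
    hd = 1.0 - float(np.sum(x * x))
    if unbiased:
        hd *= n / (n - 1.0)
    return hd


def estimate_all(
    cells: list[BandCell],
    records: list[SequenceRecord],
    unbiased: bool = True,
) -> pd.DataFrame:
    """Per-cell diversity table for cells that passed the inclusion filters.

    Alignment-site filtering is done once per species across all its cells'
    sequences, so every band estimate of a species shares one site set and
    stays comparable.  Output rows are ordered by (species_id, band).
    """
    if not cells:
        raise ValueError("no cells to estimate")
    recmap = {r.accession: r for r in records}
    by_species: dict[str, list[BandCell]] = {}
    for cell in cells:
        by_species.setdefault(cell.species_id, []).append(cell)
    rows = []
    for sp in sorted(by_species):
        sp_cells = sorted(by_species[sp], key=lambda c: c.band)
        accessions = [acc for c in sp_cells for acc in c.record_refs]
        missing = [a for a in accessions if a not in recmap]
        if missing:
            raise ValueError(f"species {sp!r}: accessions without records {missing[:5]}")
        seqs = [recmap[a].sequence for a in accessions]
        try:
            filtered, L, _ = filter_alignment_sites(seqs)
        except ValueError as exc:
            raise ValueError(f"species {sp!r}: {exc}") from exc
        filt_map = dict(zip(accessions, filtered))
        for cell in sp_cells:
            cell_seqs = [filt_map[a] for a in cell.record_refs]
            sample = collapse_haplotypes(cell_seqs, sp, cell.band)
            try:
                pi = nucleotide_diversity(sample, unbiased=unbiased)
                hd = haplotype_diversity(sample, unbiased=unbiased)
            except ValueError as exc:
                raise ValueError(
                    f"cell ({sp!r}, band {cell.band}): {exc}"
                ) from exc
            rows.append((sp, cell.band, sample.n, L, pi, hd))
    return pd.DataFrame(
        rows, columns=["species_id", "band", "n", "L", "pi", "hd"]
    )
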