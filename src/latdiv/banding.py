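"""One-degree latitudinal banding, inclusion filters, sample-size QC.

Sampling locations are pooled into one-degree latitudinal bands before
diversity estimation.  Bands are signed integer degrees by default (hemisphere
retained; 23°34'S and 23°12'S both fall in band -23); an absolute mode folds
the hemispheres together for sensitivity analyses.  Inclusion filters mirror
common macrogenetics practice: a (species, band) cell needs at least ``min_n``
sequences, and a species must retain at least ``min_bands`` distinct bands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from latdiv.seqdata import SequenceRecord


@dataclass
class BandCell:
    species_id: str
    band: int
    record_refs: list[str]

    @property
    def n(self) -> int:
        return len(self.record_refs)

    def __post_init__(self):
        if not self.record_refs:
            raise ValueError("BandCell requires at least one record")
        if not -90 <= self.band <= 90:
            raise ValueError(f"band {self.band} out of [-90, 90]")


@dataclass
class FilterReport:
    dropped_cells: list[tuple[str, int, int, str]]
    dropped_species: list[tuple[str, int, str]]
    retained_cells: int
    unique_bands: int


@dataclass
class QCReport:
    """Sample-size quality control: OLS of a diversity metric on cell n."""

    metric: str
    slope: float
    intercept: float
    p_value: float
    n_used: int
    excluded_rows: list[int]
    iterations: int


def assign_band(latitude: float, absolute: bool = False) -> int:
    """Map a signed decimal latitude to its one-degree band.

    band = sign(latitude) * floor(|latitude|): minutes are discarded and the
    hemisphere is kept in the sign, so sub-degree locations of either
    hemisphere share the equatorial band 0.  ``absolute=True`` drops the sign.
    """
    lat = float(latitude)
    if not np.isfinite(lat):
        raise ValueError(f"non-finite latitude {latitude!r}")
    if not -90 <= lat <= 90:
        raise ValueError(f"latitude {lat} out of [-90, 90]")
    mag = math.floor(abs(lat))
    if absolute or mag == 0:
        return mag
    return mag if lat > 0 else -mag


def build_cells(records: list[SequenceRecord], absolute: bool = False) -> list[BandCell]:
    """Group records into (species, band) cells, ordered deterministically."""
    if not records:
        raise ValueError("no records to band")
    grouped: dict[tuple[str, int], list[str]] = {}
    for rec in records:
        key = (rec.species_id, assign_band(rec.latitude, absolute=absolute))
        grouped.setdefault(key, []).append(rec.accession)
    return [
        BandCell(species_id=sp, band=b, record_refs=refs)
        for (sp, b), refs in sorted(grouped.items())
    ]


def apply_species_filters(
    cells: list[BandCell], min_n: int = 3, min_bands: int = 4
) -> tuple[list[BandCell], FilterReport]:
    """Drop thin cells, then species with too few surviving bands.

    Cells with fewer than ``min_n`` sequences go first; species whose
    surviving distinct-band count is below ``min_bands`` are then removed
    entirely.  Every drop is recorded with its reason.
    """
    if not cells:
        raise ValueError("no cells to filter")
    ordered = sorted(cells, key=lambda c: (c.species_id, c.band))
    dropped_cells: list[tuple[str, int, int, str]] = []
    survivors: list[BandCell] = []
    for cell in ordered:
        if cell.n < min_n:
            dropped_cells.append(
                (cell.species_id, cell.band, cell.n, f"n < {min_n}")
            )
        else:
            survivors.append(cell)
    bands_per_species: dict[str, set[int]] = {}
    for cell in survivors:
        bands_per_species.setdefault(cell.species_id, set()).add(cell.band)
    dropped_species: list[tuple[str, int, str]] = []
    bad_species: set[str] = set()
    for sp in sorted({c.species_id for c in ordered}):
        n_bands = len(bands_per_species.get(sp, ()))
        if n_bands < min_bands:
            bad_species.add(sp)
            dropped_species.append((sp, n_bands, "insufficient bands"))
    retained = [c for c in survivors if c.species_id not in bad_species]
    for cell in survivors:
        if cell.species_id in bad_species:
            dropped_cells.append(
                (cell.species_id, cell.band, cell.n, "species dropped")
            )
    report = FilterReport(
        dropped_cells=dropped_cells,
        dropped_species=dropped_species,
        retained_cells=len(retained),
        unique_bands=len({c.band for c in retained}),
    )
    return retained, report


def multispecies_band_filter(estimates: pd.DataFrame) -> pd.DataFrame:
    """Keep only bands represented by more than one species.

    Applied to the pooled (total genetic diversity) analysis only — never to
    the intraspecific fits, which use every band of each species.
    """
    counts = estimates.groupby("band")["species_id"].nunique()
    keep = counts[counts >= 2].index
    return estimates[estimates["band"].isin(keep)].reset_index(drop=True)


def _externally_studentized(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    XtX_inv = np.linalg.inv(X.T @ X)
    h = np.einsum("ij,jk,ik->i", X, XtX_inv, X)
    sse = float(resid @ resid)
    with np.errstate(invalid="ignore", divide="ignore"):
        s2_i = (sse - resid**2 / (1.0 - h)) / (n - p - 1)
        t = resid / np.sqrt(np.clip(s2_i, 1e-300, None) * (1.0 - h))
    return t, beta, resid


def sample_size_qc(
    estimates: pd.DataFrame,
    metric: str,
    outlier_threshold: float = 3.0,
    max_iter: int = 20,
) -> QCReport:
    """Check that per-cell sample size does not predict the diversity metric.

    OLS of ``metric`` on cell ``n``, iteratively excluding rows whose
    externally studentized residual exceeds ``outlier_threshold`` in absolute
    value (a reproducible stand-in for visual residual inspection), then
    reporting the slope and its two-sided p-value.
    """
    from scipy import stats

    if metric not in estimates.columns or "n" not in estimates.columns:
        raise ValueError(f"estimates must carry columns 'n' and {metric!r}")
    if len(estimates) < 10:
        raise ValueError("sample-size QC needs at least 10 rows")
    y_all = estimates[metric].to_numpy(dtype=float)
    x_all = estimates["n"].to_numpy(dtype=float)
    active = np.arange(len(y_all))
    excluded: list[int] = []
    iterations = 0
    for _ in range(max_iter):
        if active.size < 4:
            break
        X = np.column_stack([np.ones(active.size), x_all[active]])
        t, _, _ = _externally_studentized(y_all[active], X)
        bad = np.abs(t) > outlier_threshold
        if not bad.any():
            break
        excluded.extend(active[bad].tolist())
        active = active[~bad]
        iterations += 1
    if active.size < 4:
        raise ValueError("sample-size QC excluded (nearly) all rows")
    X = np.column_stack([np.ones(active.size), x_all[active]])
    yv = y_all[active]
    beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
    resid = yv - X @ beta
    dof = active.size - 2
    if dof <= 0 or np.ptp(x_all[active]) == 0:
        slope_se = np.nan
        p_value = np.nan
    else:
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.inv(X.T @ X)
        slope_se = math.sqrt(cov[1, 1])
        if slope_se == 0.0:
            p_value = 1.0 if beta[1] == 0 else 0.0
        else:
            t_stat = beta[1] / slope_se
            p_value = 2.0 * stats.t.sf(abs(t_stat), dof)
    return QCReport(
        metric=metric,
        slope=float(beta[1]),
        intercept=float(beta[0]),
        p_value=float(p_value),
        n_used=int(active.size),
        excluded_rows=sorted(excluded),
        iterations=iterations,
    )
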