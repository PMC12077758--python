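"""Synthetic datasets with known ground truth for every pipeline stage.

Three generators share one configuration:

* ``simulate_response_table`` draws band-level diversity responses directly
  from the Gaussian random-intercept quadratic model the pooled analysis
  assumes — the clean path for coefficient-recovery tests.
* ``simulate_sequences`` emits a FASTA + metadata dataset: per (species,
  band) cell, haplotype frequencies follow a Chinese-restaurant partition
  whose concentration, and a star genealogy whose private-mutation rate, are
  tied monotonically to a latent diversity surface mu(species, band) =
  exp(b0 + b1 z + b2 z^2 + a_s) — an equatorial hump on the log scale.  This
  is deliberately *not* a full coalescent: no recombination, an
  infinite-sites approximation on finite L with collision re-draws — cheap,
  monotone in its parameters, and sufficient for testing the estimators and
  trend recovery.
* ``simulate_env_fields`` builds six environmental covariates named after
  the Bio-ORACLE layers, with sea surface temperature declining away from
  the equator and dissolved oxygen inversely tied to it (one strongly
  collinear pair, as in tropical marine data), the rest weakly structured.

Default sizes mirror a tropical-Atlantic macrogenetics compilation:
23 species/lineages inside 36N-32S, ~8 one-degree bands each, 3-15
sequences per band (~170-190 cells).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from latdiv.seqdata import SequenceRecord

_BASES = np.array(list("ACGT"))

ENV_COLUMNS = [
    "BO_sstmean",
    "BO_dissox",
    "BO_salinity",
    "BO2_curvelmean_bdmean",
    "BO_chlomean",
    "BO22_ph",
]


@dataclass
class SimConfig:
    """Study-shaped simulation parameters.

    Band-level responses use the identity-scale Gaussian model
    y = b0 + b1 z + b2 z^2 + a_s + eps on the z-scored band latitude.
    Sequence-level diversity uses log-scale coefficients (``beta_seq``) so
    the latent surface mu stays positive.  ``env_effects`` optionally adds
    linear environmental effects (on z-scored covariates) to the band-level
    pi response for driver-recovery experiments.
    """

    n_species: int = 23
    lat_min: int = -32
    lat_max: int = 36
    bands_min: int = 4
    bands_max: int = 12
    n_min: int = 3
    n_max: int = 15
    # band-level Gaussian responses
    beta_pi: tuple[float, float, float] = (0.012, 0.0, -0.004)
    sigma2_alpha_pi: float = 9e-4
    sigma2_eps_pi: float = 3e-4
    beta_hd: tuple[float, float, float] = (0.80, 0.0, -0.08)
    sigma2_alpha_hd: float = 0.02
    sigma2_eps_hd: float = 0.015
    env_effects: dict[str, float] = field(default_factory=dict)
    # sequence-level latent diversity surface (log scale)
    seq_length: int = 600
    beta_seq: tuple[float, float, float] = (math.log(0.008), 0.0, -0.5)
    sigma2_alpha_seq: float = 0.09
    theta0: float = 1.5
    # environmental field
    env_r_target: float = -0.7
    env_do_noise: float = 0.06
    chl_mu_effect: float = 0.0

    def validate(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if not (-90 <= self.lat_min < self.lat_max <= 90):
            raise ValueError("latitude range must satisfy -90 <= min < max <= 90")
        if self.bands_min < 1 or self.bands_max < self.bands_min:
            raise ValueError("invalid bands-per-species range")
        if self.bands_max > self.lat_max - self.lat_min + 1:
            raise ValueError("bands_max exceeds the latitude span")
        if self.n_min < 1 or self.n_max < self.n_min:
            raise ValueError("invalid per-band n range")
        for name in ("sigma2_alpha_pi", "sigma2_eps_pi", "sigma2_alpha_hd",
                     "sigma2_eps_hd", "sigma2_alpha_seq"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.seq_length < 1 or self.theta0 < 0:
            raise ValueError("seq_length >= 1 and theta0 >= 0 required")
        if not -1.0 <= self.env_r_target <= 0.0:
            raise ValueError("env_r_target must be in [-1, 0]")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class SimTruth:
    """Everything needed to recompute the expectations used in tests."""

    seed: int
    config_hash: str
    band_scale: tuple[float, float]  # (mean, sd) of the z-scoring of bands
    beta_pi: tuple[float, float, float] | None = None
    beta_hd: tuple[float, float, float] | None = None
    intercepts_pi: dict[str, float] = field(default_factory=dict)
    intercepts_hd: dict[str, float] = field(default_factory=dict)
    env_effects: dict[str, float] = field(default_factory=dict)
    beta_seq: tuple[float, float, float] | None = None
    intercepts_seq: dict[str, float] = field(default_factory=dict)
    mu: dict[str, float] = field(default_factory=dict)  # "species:band" -> mu

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=1)


@dataclass
class SequenceDataset:
    records: list[SequenceRecord]
    metadata: pd.DataFrame
    truth: SimTruth

    def write(self, out_dir) -> dict[str, Path]:
        """Write FASTA + metadata TSV + truth JSON, each tagged with the
        config hash and seed for bit-identical regeneration."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tag = f"cfg={self.truth.config_hash} seed={self.truth.seed}"
        fasta = out / "sequences.fasta"
        with open(fasta, "w") as fh:
            for rec in self.records:
                fh.write(f">{rec.accession} {rec.species_id} {tag}\n")
                fh.write(rec.sequence + "\n")
        meta = out / "metadata.tsv"
        with open(meta, "w") as fh:
            fh.write(f"# {tag}\n")
            self.metadata.to_csv(fh, sep="\t", index=False)
        truth = out / "truth.json"
        truth.write_text(self.truth.to_json())
        return {"fasta": fasta, "metadata": meta, "truth": truth}


def _species_layout(config: SimConfig, rng: np.random.Generator):
    """Contiguous one-degree band ranges and per-band sample sizes."""
    cells = []
    for s in range(config.n_species):
        sp = f"sp{s:02d}"
        n_bands = int(rng.integers(config.bands_min, config.bands_max + 1))
        start = int(rng.integers(config.lat_min,
                                 config.lat_max - n_bands + 2))
        for band in range(start, start + n_bands):
            n = int(rng.integers(config.n_min, config.n_max + 1))
            cells.append((sp, band, n))
    return cells


def _zscore_bands(bands: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    mean = float(bands.mean())
    sd = float(bands.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate layout: a single band across all cells")
    return (bands - mean) / sd, (mean, sd)


def simulate_env_fields(
    config: SimConfig,
    seed: int,
    bands: np.ndarray | None = None,
    max_redraws: int = 100,
) -> pd.DataFrame:
    """Per-band environmental covariates with one collinear pair.

    SST decreases away from the equator; dissolved oxygen is a negative
    affine function of SST plus small noise, redrawn until the realized
    Pearson r(SST, DO) is at or below ``env_r_target``.  Salinity, current
    velocity and pH are weakly structured noise kept pairwise |r| < 0.5;
    chlorophyll-a can carry a configured association with the latent
    diversity surface.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    if bands is None:
        bands = np.arange(config.lat_min, config.lat_max + 1)
    bands = np.asarray(sorted(set(int(b) for b in bands)))
    m = len(bands)
    for _ in range(max_redraws):
        sst = 28.0 - 0.14 * np.abs(bands) + rng.normal(0.0, 0.6, m)
        do = 7.5 - 0.2 * sst + rng.normal(0.0, config.env_do_noise, m)
        sal = 36.0 + rng.normal(0.0, 0.5, m)
        cur = 0.15 + rng.normal(0.0, 0.05, m)
        ph = 8.05 + rng.normal(0.0, 0.04, m)
        chl = 0.45 + rng.normal(0.0, 0.12, m)
        if config.chl_mu_effect != 0.0:
            z, _ = _zscore_bands(bands.astype(float))
            surface = np.exp(config.beta_seq[1] * z + config.beta_seq[2] * z**2)
            surface = (surface - surface.mean()) / surface.std(ddof=1)
            chl = chl + config.chl_mu_effect * surface
        if config.env_do_noise == 0.0:
            r_sst_do = -1.0
        else:
            r_sst_do = float(np.corrcoef(sst, do)[0, 1])
        weak = np.corrcoef(np.vstack([sal, cur, ph]))
        weak_ok = np.all(np.abs(weak[np.triu_indices(3, 1)]) < 0.5)
        if r_sst_do <= config.env_r_target and weak_ok:
            return pd.DataFrame({
                "band": bands,
                "lat": bands.astype(float),
                "lon": rng.uniform(-60.0, -35.0, m),
                "BO_sstmean": sst,
                "BO_dissox": do,
                "BO_salinity": sal,
                "BO2_curvelmean_bdmean": cur,
                "BO_chlomean": chl,
                "BO22_ph": ph,
            })
    raise ValueError(
        "environmental constraints unmet after redraws; "
        "relax env_r_target or reduce env_do_noise"
    )


def simulate_response_table(
    config: SimConfig, seed: int
) -> tuple[pd.DataFrame, SimTruth]:
    """Band-level diversity responses drawn from the assumed mixed model.

    One row per (species, band) cell with columns ``pi`` and ``hd`` drawn
    independently from their quadratic-latitude random-intercept models, the
    per-cell sample size ``n``, and the six environmental covariates of the
    cell's band.  Configured ``env_effects`` (on z-scored covariates) are
    added to the pi response.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    cells = _species_layout(config, rng)
    species = sorted({c[0] for c in cells})
    bands = np.array([c[1] for c in cells], dtype=float)
    z, band_scale = _zscore_bands(bands)
    a_pi = {sp: rng.normal(0.0, math.sqrt(config.sigma2_alpha_pi))
            for sp in species}
    a_hd = {sp: rng.normal(0.0, math.sqrt(config.sigma2_alpha_hd))
            for sp in species}
    b0p, b1p, b2p = config.beta_pi
    b0h, b1h, b2h = config.beta_hd
    df = pd.DataFrame({
        "species_id": [c[0] for c in cells],
        "band": [c[1] for c in cells],
        "n": [c[2] for c in cells],
        "z": z,
    })
    env = simulate_env_fields(config, int(rng.integers(2**31)),
                              bands=np.unique(df["band"]))
    df = df.merge(env.drop(columns=["lat", "lon"]), on="band", how="left")
    mu_pi = b0p + b1p * z + b2p * z**2 + np.array([a_pi[s] for s in df["species_id"]])
    mu_hd = b0h + b1h * z + b2h * z**2 + np.array([a_hd[s] for s in df["species_id"]])
    for var, coef in config.env_effects.items():
        col = df[var].to_numpy(dtype=float)
        col_z = (col - col.mean()) / col.std(ddof=1)
        mu_pi = mu_pi + coef * col_z
    df["pi"] = mu_pi + rng.normal(0.0, math.sqrt(config.sigma2_eps_pi), len(df))
    df["hd"] = mu_hd + rng.normal(0.0, math.sqrt(config.sigma2_eps_hd), len(df))
    truth = SimTruth(
        seed=seed,
        config_hash=config.hash(),
        band_scale=band_scale,
        beta_pi=config.beta_pi,
        beta_hd=config.beta_hd,
        intercepts_pi=a_pi,
        intercepts_hd=a_hd,
        env_effects=dict(config.env_effects),
    )
    return df, truth


def _crp_partition(n: int, theta: float, rng: np.random.Generator) -> list[int]:
    """Chinese-restaurant partition of n items at concentration theta."""
    counts: list[int] = []
    for i in range(n):
        if counts and rng.random() >= theta / (theta + i):
            probs = np.asarray(counts, dtype=float) / i
            j = int(rng.choice(len(counts), p=probs))
            counts[j] += 1
        else:
            counts.append(1)
    return counts


def _mutate(reference: np.ndarray, sites: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    seq = reference.copy()
    for s in sites:
        current = seq[s]
        choices = [b for b in "ACGT" if b != current]
        seq[s] = choices[int(rng.integers(3))]
    return seq


def simulate_sequences(config: SimConfig, seed: int) -> SequenceDataset:
    """Sequence-level dataset under a star genealogy with private mutations.

    Per cell, the haplotype partition comes from a Chinese-restaurant scheme
    with concentration theta(s, band) = theta0 * mu / exp(b0_seq); each
    distinct haplotype carries Poisson(lambda) private substitutions from
    the species reference with lambda = mu * L / 2, so the expected
    between-haplotype per-site distance is ~mu.  Haplotype sequences are
    redrawn on collision (up to 100 tries) to approximate infinite sites.
    Individuals get uniform sub-degree latitudes inside their band with the
    correct hemisphere.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    cells = _species_layout(config, rng)
    species = sorted({c[0] for c in cells})
    bands = np.array([c[1] for c in cells], dtype=float)
    z, band_scale = _zscore_bands(bands)
    a_seq = {sp: rng.normal(0.0, math.sqrt(config.sigma2_alpha_seq))
             for sp in species}
    b0, b1, b2 = config.beta_seq
    L = config.seq_length
    references = {
        sp: _BASES[rng.integers(4, size=L)] for sp in species
    }
    records: list[SequenceRecord] = []
    meta_rows = []
    mu_map: dict[str, float] = {}
    for (sp, band, n), z_cell in zip(cells, z):
        mu = math.exp(b0 + b1 * z_cell + b2 * z_cell**2 + a_seq[sp])
        mu_map[f"{sp}:{band}"] = mu
        theta = config.theta0 * mu / math.exp(b0)
        lam = mu * L / 2.0
        counts = _crp_partition(n, theta, rng)
        ref = references[sp]
        haplotypes: list[str] = []
        seen: set[str] = set()
        for _ in counts:
            for _attempt in range(100):
                m = int(rng.poisson(lam))
                sites = rng.choice(L, size=min(m, L), replace=False)
                hap = "".join(_mutate(ref, sites, rng))
                if hap not in seen:
                    break
            seen.add(hap)
            haplotypes.append(hap)
        i = 0
        for hap, c in zip(haplotypes, counts):
            for _ in range(c):
                acc = f"{sp.upper()}B{band:+03d}I{i:03d}"
                u = rng.uniform(0.0, 0.999)
                if band > 0:
                    lat = band + u
                elif band < 0:
                    lat = band - u
                else:
                    lat = rng.uniform(-0.999, 0.999)
                lon = rng.uniform(-60.0, -35.0)
                records.append(SequenceRecord(
                    accession=acc, species_id=sp, latitude=lat,
                    longitude=lon, sequence=hap,
                ))
                meta_rows.append((acc, sp, lat, lon, band))
                i += 1
    metadata = pd.DataFrame(
        meta_rows,
        columns=["accession", "species_id", "latitude", "longitude", "band"],
    )
    truth = SimTruth(
        seed=seed,
        config_hash=config.hash(),
        band_scale=band_scale,
        beta_seq=config.beta_seq,
        intercepts_seq=a_seq,
        mu=mu_map,
    )
    return SequenceDataset(records=records, metadata=metadata, truth=truth)
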