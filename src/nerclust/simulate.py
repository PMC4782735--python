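"""Simulated species occurrence matrices with a known regional structure.

The generator emulates how biogeographic occurrence data arise: a regional
species pool contains *cosmopolitan* species shared by every region and
*endemic* species restricted to a single region; the endemicity proportion
``e`` controls how distinct the regions are (e=0: identical pools, no
cluster signal; e=1: disjoint pools). A locality's sample is drawn by
giving every pool species a fresh log-normal relative abundance — so each
locality has a few dominant species, many rare ones, and species missed
entirely — and then drawing a fixed number of specimens with replacement
in proportion to those abundances. The specimen count per locality is the
sampling-intensity dial: few specimens give sparse, noisy presences.

The true region of every site is recorded, so cluster-recovery accuracy
can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distances import OccurrenceMatrix

__all__ = ["SimParams", "build_species_pools", "sample_locality", "sim_occ"]

_MAX_REDRAWS = 100


@dataclass(frozen=True)
class SimParams:
    """Parameters of the occurrence simulator.

    Attributes
    ----------
    n_species : int
        Total species pool size across all regions.
    n_regions : int
        Number of regions, i.e. true clusters (>= 2).
    sites_per_region : int
        Localities sampled per region.
    endemicity : float in [0, 1]
        Proportion of all species endemic to exactly one region; endemics
        are split as evenly as possible across regions (earlier regions get
        any remainder), the rest are cosmopolitan.
    specimens_per_site : int
        Specimens drawn per locality (fixed per-site count; the sampling
        intensity).
    lognormal_meanlog, lognormal_sdlog : float
        Shape of the per-locality log-normal relative-abundance draw;
        sdlog=1.5 gives a few dominant species and a long rare tail.
    seed : int or None
        RNG seed; the whole matrix is reproducible given the parameters.
    """

    n_species: int = 100
    n_regions: int = 3
    sites_per_region: int = 30
    endemicity: float = 0.5
    specimens_per_site: int = 50
    lognormal_meanlog: float = 0.0
    lognormal_sdlog: float = 1.5
    seed: int | None = None

    def __post_init__(self):
        if self.n_regions < 2:
            raise ValueError("n_regions must be >= 2")
        if not (0.0 <= self.endemicity <= 1.0):
            raise ValueError("endemicity must be in [0, 1]")
        if self.specimens_per_site < 1:
            raise ValueError("specimens_per_site must be >= 1")
        if self.n_species < 1 or self.sites_per_region < 1:
            raise ValueError("n_species and sites_per_region must be >= 1")


def build_species_pools(p: SimParams) -> dict[int, np.ndarray]:
    """Deterministic region -> species-index pools.

    round(e * n_species) species are endemic, assigned to regions in
    contiguous blocks as evenly as possible (earlier regions receive the
    remainder); the remaining species belong to every pool.
    """
    n_endemic = int(round(p.endemicity * p.n_species))
    cosmopolitan = np.arange(n_endemic, p.n_species)
    base, extra = divmod(n_endemic, p.n_regions)
    pools: dict[int, np.ndarray] = {}
    start = 0
    for r in range(p.n_regions):
        size = base + (1 if r < extra else 0)
        endemic = np.arange(start, start + size)
        start += size
        pool = np.concatenate([endemic, cosmopolitan])
        if pool.size == 0:
            raise ValueError(
                f"region {r} has an empty species pool "
                f"(n_species={p.n_species}, e={p.endemicity}, n_regions={p.n_regions})"
            )
        pools[r] = pool
    return pools


def sample_locality(pool: np.ndarray, p: SimParams, rng: np.random.Generator) -> np.ndarray:
    """Specimen counts over all species for one locality.

    A fresh log-normal relative abundance is drawn per pool species, then
    ``specimens_per_site`` specimens are drawn with replacement in
    proportion to it (a multinomial), so column sums equal the specimen
    count exactly. Species outside the pool stay 0; absences inside the
    pool arise naturally from the skewed abundances and finite sampling.
    """
    pool = np.asarray(pool)
    if pool.size == 0:
        raise ValueError("species pool is empty")
    for _ in range(_MAX_REDRAWS):
        abundance = rng.lognormal(p.lognormal_meanlog, p.lognormal_sdlog, size=pool.size)
        draws = rng.multinomial(p.specimens_per_site, abundance / abundance.sum())
        if draws.sum() > 0:  # always true for a fixed positive draw count
            counts = np.zeros(p.n_species, dtype=np.int64)
            counts[pool] = draws
            return counts
    raise RuntimeError(f"locality empty after {_MAX_REDRAWS} redraws")


def sim_occ(p: SimParams) -> OccurrenceMatrix:
    """Simulate a full occurrence matrix with known regional truth labels.

    Columns are grouped by region (region 0 sites first); ``true_regions``
    records the region of every site.
    """
    rng = np.random.default_rng(p.seed)
    pools = build_species_pools(p)
    columns, truth, site_ids = [], [], []
    for r in range(p.n_regions):
        for s in range(p.sites_per_region):
            columns.append(sample_locality(pools[r], p, rng))
            truth.append(r)
            site_ids.append(f"R{r + 1}_S{s + 1}")
    counts = np.column_stack(columns)
    df = pd.DataFrame(
        counts,
        index=[f"sp{i + 1}" for i in range(p.n_species)],
        columns=site_ids,
    )
    return OccurrenceMatrix(df, true_regions=np.asarray(truth, dtype=np.int64))
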