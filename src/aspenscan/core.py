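"""Core in-memory containers shared across the package.

Conventions
-----------
* Physical coordinates are 1-based inclusive on every public surface
  (matching VCF); internal window arithmetic is 0-based half-open.
* Haplotype alleles are polarized: 0 = ancestral, 1 = derived, -1 = missing.
* Genotype dosages count the alternate (or derived, when polarized)
  allele: 0/1/2, with -1 for missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1


@dataclass
class SweepModel:
    """Parameters of a hard selective sweep in a panmictic diploid population.

    Attributes
    ----------
    Ne : int
        Diploid effective population size.
    mu : float
        Mutation rate per bp per generation.
    r : float
        Recombination rate per bp per generation.
    L : int
        Region length in bp.
    s : float
        Selection coefficient of the derived homozygote; heterozygote
        fitness is 1 + s/2 (additive selection).
    T_fix : float
        Time since fixation of the beneficial allele, in units of 4*Ne
        generations.
    n_hap : int
        Number of sampled haplotypes.
    sweep_pos : int
        1-based position of the selected site.
    """

    Ne: int
    mu: float
    r: float
    L: int
    s: float
    T_fix: float
    n_hap: int
    sweep_pos: int

    def __post_init__(self) -> None:
        if self.Ne < 2:
            raise ValueError(f"Ne must be >= 2, got {self.Ne}")
        if not (0 < self.s <= 1):
            raise ValueError(f"s must be in (0, 1], got {self.s}")
        if self.T_fix < 0:
            raise ValueError(f"T_fix must be >= 0, got {self.T_fix}")
        if not (1 <= self.sweep_pos <= self.L):
            raise ValueError("sweep_pos must lie in [1, L]")
        if self.theta <= 0:
            raise ValueError("theta = 4*Ne*mu*L must be > 0")
        if self.rho < 0:
            raise ValueError("rho = 4*Ne*r*L must be >= 0")
        if self.n_hap < 2:
            raise ValueError("n_hap must be >= 2")

    @property
    def theta(self) -> float:
        """Scaled region mutation rate 4*Ne*mu*L."""
        return 4.0 * self.Ne * self.mu * self.L

    @property
    def rho(self) -> float:
        """Scaled region recombination rate 4*Ne*r*L."""
        return 4.0 * self.Ne * self.r * self.L

    @classmethod
    def from_scaled(
        cls,
        theta: float,
        rho: float,
        L: int,
        s: float,
        T_fix: float,
        n_hap: int,
        Ne: int = 92_000,
        sweep_pos: int | None = None,
    ) -> "SweepModel":
        """Build a model from region-scaled theta/rho.

        mu and r are back-computed so 4*Ne*mu*L = theta and
        4*Ne*r*L = rho; Ne only fixes the time scale.
        """
        mu = theta / (4.0 * Ne * L)
        r = rho / (4.0 * Ne * L)
        if sweep_pos is None:
            sweep_pos = L // 2
        return cls(Ne=Ne, mu=mu, r=r, L=L, s=s, T_fix=T_fix,
                   n_hap=n_hap, sweep_pos=sweep_pos)


@dataclass
class Trajectory:
    """Beneficial-allele frequency path, backward in time from fixation.

    ``freqs[0] == 1.0`` (fixation, the present end of the sweep phase);
    the last nonzero entry is ``1/(2*N_sim)`` (the generation the mutation
    arose) and the final entry is 0.
    """

    freqs: np.ndarray
    N_sim: int

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f[0] != 1.0:
            raise ValueError("trajectory must start (backward) at fixation")
        if f[-1] != 0.0:
            raise ValueError("trajectory must end at loss (0)")
        nz = f[f > 0]
        if abs(nz[-1] - 1.0 / (2 * self.N_sim)) > 1e-12:
            raise ValueError("last nonzero frequency must be 1/(2*N_sim)")
        if np.any((f < 0) | (f > 1)):
            raise ValueError("frequencies must lie in [0, 1]")
        self.freqs = f


@dataclass
class HaplotypeMatrix:
    """Phased, polarized haplotypes over biallelic sites.

    ``alleles`` is n_hap x n_sites with values in {0, 1, MISSING};
    ``positions`` are strictly increasing 1-based bp coordinates.
    """

    alleles: np.ndarray
    positions: np.ndarray
    region_length: int

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be 2-D (n_hap x n_sites)")
        if self.alleles.shape[1] != self.positions.size:
            raise ValueError("positions length must match site count")
        if self.positions.size:
            if np.any(np.diff(self.positions) <= 0):
                raise ValueError("positions must be strictly increasing")
            if self.positions[0] < 1 or self.positions[-1] > self.region_length:
                raise ValueError("positions must lie in [1, region_length]")

    @property
    def n_hap(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def derived_freq(self) -> np.ndarray:
        """Per-site derived-allele frequency over non-missing haplotypes."""
        a = self.alleles
        valid = a != MISSING
        with np.errstate(invalid="ignore"):
            return np.where(valid, a, 0).sum(0) / valid.sum(0)


@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix with per-site allele metadata.

    ``dosages``: n_individuals x n_sites in {0, 1, 2, MISSING}.
    ``sites``: DataFrame with at least columns chrom, pos (1-based), ref,
    alt; optional 'aa' (ancestral allele string, '.' = unknown).
    """

    dosages: np.ndarray
    sites: pd.DataFrame
    individuals: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D")
        if len(self.sites) != self.dosages.shape[1]:
            raise ValueError("sites table must match dosage columns")
        if not self.individuals:
            self.individuals = [f"ind{i:03d}" for i in range(self.dosages.shape[0])]
        dup = self.sites.duplicated(subset=["chrom", "pos"])
        if dup.any():
            raise ValueError("positions must be unique within a chromosome")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    def maf(self) -> np.ndarray:
        """Per-site minor-allele frequency over non-missing genotypes."""
        d = self.dosages
        valid = d != MISSING
        n = 2 * valid.sum(0)
        with np.errstate(invalid="ignore"):
            p = np.where(valid, d, 0).sum(0) / n
        return np.minimum(p, 1 - p)

    def call_rate(self) -> np.ndarray:
        return (self.dosages != MISSING).mean(0)


@dataclass
class CohortMetadata:
    """Per-individual study metadata.

    DataFrame-backed: columns id, population (1..n_pops), latitude (deg N),
    environment_pc1 (unitless), genetic_value (bud-set day).
    """

    table: pd.DataFrame

    REQUIRED = ("id", "population", "latitude", "environment_pc1", "genetic_value")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"metadata missing required column {col!r}")
        if not np.isfinite(self.table["genetic_value"].to_numpy(float)).all():
            raise ValueError("genetic_value must be finite")
        pops = self.table.groupby("population")["latitude"].mean()
        if not pops.is_monotonic_increasing:
            raise ValueError("population latitudes must be ordered with population id")

    @property
    def n_pops(self) -> int:
        return self.table["population"].nunique()

    def __len__(self) -> int:
        return len(self.table)
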