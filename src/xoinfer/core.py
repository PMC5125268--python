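"""Core domain types shared across the pipeline.

The pipeline moves through a small set of containers: genotypes and
pedigrees come in (``GenotypeTable``, ``PedigreeTable``), crossovers are
detected per meiosis (``CrossoverRecord``, ``Meiosis``), converted to
genetic coordinates against a sex-specific map (``ChromosomeMap``,
``IntervalData``) and finally fitted under the Housworth-Stahl
interference-escape model (``HSParameters``, ``EstimateRecord``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1  # sentinel genotype dosage

__all__ = [
    "MISSING",
    "HSParameters",
    "IntervalData",
    "CrossoverRecord",
    "Meiosis",
    "ChromosomeMap",
    "GenotypeTable",
    "PedigreeTable",
    "EstimateRecord",
]


@dataclass(frozen=True)
class HSParameters:
    """Housworth-Stahl model parameters.

    nu : interference strength, the shape of the gamma renewal process
        governing chiasma spacing (nu = 1 means no interference).
    p : escape fraction, the proportion of crossovers produced by the
        interference-free Poisson pathway.
    """

    nu: float
    p: float

    def __post_init__(self) -> None:
        if not (self.nu > 0 and np.isfinite(self.nu)):
            raise ValueError(f"nu must be positive and finite, got {self.nu}")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p must lie in [0, 1], got {self.p}")

    @property
    def q(self) -> float:
        """Interference-pathway crossover rate per Morgan (1 - p)."""
        return 1.0 - self.p


@dataclass(frozen=True)
class IntervalData:
    """Ordered crossover positions on one chromosome of one meiosis.

    Positions are in Morgans on [0, L].  The gaps y0 (chromosome start to
    first crossover), y1..y_{n-1} (between crossovers) and the censored
    terminal gap L - y_last are what the interference likelihood consumes.
    """

    positions: tuple[float, ...]
    length: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if self.length < 0:
            raise ValueError("chromosome length must be >= 0")
        if pos.size:
            if np.any(pos < 0) or np.any(pos > self.length):
                raise ValueError("crossover positions must lie in [0, L]")
            if np.any(np.diff(pos) <= 0):
                raise ValueError("crossover positions must be strictly increasing")

    @property
    def n(self) -> int:
        return len(self.positions)

    @property
    def gaps(self) -> np.ndarray:
        """All gaps including the censored terminal one; sums to L."""
        pos = np.asarray(self.positions, dtype=float)
        edges = np.concatenate([[0.0], pos, [self.length]])
        return np.diff(edges)


@dataclass(frozen=True)
class CrossoverRecord:
    """One detected crossover, localized to its flanking informative markers."""

    meiosis_id: str
    chromosome: str
    left_marker: str
    left_bp: int
    right_marker: str
    right_bp: int
    midpoint_cm: float

    def __post_init__(self) -> None:
        if self.left_bp >= self.right_bp:
            raise ValueError(
                f"left bp {self.left_bp} must be < right bp {self.right_bp}"
            )


@dataclass
class Meiosis:
    """One parent -> offspring transmission with its detected crossovers."""

    meiosis_id: str
    parent_id: str
    offspring_id: str
    parent_sex: str  # "male" | "female"
    parent_age_months: float | None
    crossovers: dict[str, list[CrossoverRecord]] = field(default_factory=dict)

    def count(self, chromosome: str) -> int:
        return len(self.crossovers.get(chromosome, []))

    def max_count(self) -> int:
        if not self.crossovers:
            return 0
        return max(len(v) for v in self.crossovers.values())


@dataclass
class ChromosomeMap:
    """Marker positions with per-interval recombination rates for one sex.

    ``cum_cm[i]`` is the cumulative genetic position of marker i; interval
    rates are recombination fractions between adjacent markers (cM/100).
    """

    chromosome: str
    marker_ids: list[str]
    bp: np.ndarray
    interval_rates: np.ndarray  # length len(bp) - 1
    sex: str = "both"

    def __post_init__(self) -> None:
        self.bp = np.asarray(self.bp, dtype=np.int64)
        self.interval_rates = np.asarray(self.interval_rates, dtype=float)
        if len(self.marker_ids) != len(self.bp):
            raise ValueError("marker_ids and bp must have equal length")
        if self.interval_rates.shape[0] != max(len(self.bp) - 1, 0):
            raise ValueError("need one interval rate per adjacent marker pair")
        if np.any(np.diff(self.bp) <= 0):
            raise ValueError("marker bp positions must be strictly increasing")
        if np.any(self.interval_rates < 0):
            raise ValueError("interval rates must be >= 0")

    @property
    def cum_cm(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.interval_rates)]) * 100.0

    @property
    def length_cm(self) -> float:
        return float(self.interval_rates.sum() * 100.0)

    def genetic_position_cm(self, bp: np.ndarray | float) -> np.ndarray:
        """Interpolate genetic position (cM) at physical position(s) bp."""
        return np.interp(np.asarray(bp, dtype=float), self.bp.astype(float), self.cum_cm)


class GenotypeTable:
    """Samples x markers dosage matrix with a marker map.

    Dosages are 0/1/2 alt-allele counts, ``MISSING`` (-1) for no-calls.
    Markers are kept sorted by (chromosome, bp); chromosome labels are
    strings ("1".."29" for cattle autosomes).
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        marker_ids: Sequence[str],
        dosages: np.ndarray,
        chromosomes: Sequence[str],
        positions_bp: Sequence[int],
    ) -> None:
        dosages = np.asarray(dosages, dtype=np.int8)
        sample_ids = list(map(str, sample_ids))
        marker_ids = list(map(str, marker_ids))
        chromosomes = [str(c) for c in chromosomes]
        positions_bp = np.asarray(positions_bp, dtype=np.int64)
        if dosages.shape != (len(sample_ids), len(marker_ids)):
            raise ValueError("dosage matrix shape mismatch")
        if len(chromosomes) != len(marker_ids) or len(positions_bp) != len(marker_ids):
            raise ValueError("marker map length mismatch")
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(marker_ids)) != len(marker_ids):
            raise ValueError("duplicate marker ids")
        bad = ~np.isin(dosages, [0, 1, 2, MISSING])
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype code {int(dosages[i, j])} for sample "
                f"{sample_ids[i]} at marker {marker_ids[j]}"
            )
        # sort markers by (chromosome, bp); numeric chromosome labels first
        def chrom_key(c: str):
            return (0, int(c)) if c.isdigit() else (1, c)

        order = sorted(
            range(len(marker_ids)),
            key=lambda j: (chrom_key(chromosomes[j]), int(positions_bp[j])),
        )
        self.sample_ids = sample_ids
        self.marker_ids = [marker_ids[j] for j in order]
        self.dosages = dosages[:, order]
        self.chromosomes = np.array([chromosomes[j] for j in order])
        self.positions_bp = positions_bp[order]
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def sample_row(self, sample_id: str) -> np.ndarray:
        return self.dosages[self._sample_index[sample_id]]

    def has_sample(self, sample_id: str) -> bool:
        return sample_id in self._sample_index

    def marker_mask(self, chromosome: str) -> np.ndarray:
        return self.chromosomes == str(chromosome)

    def chromosome_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chromosomes:
            seen.setdefault(c, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosages, index=self.sample_ids, columns=self.marker_ids
        )


@dataclass
class PedigreeTable:
    """Three-generation family structure as a DataFrame wrapper.

    Columns: offspring, sire, dam, grandsire, parent_sex, parent_age_months.
    ``grandsire`` is the sire of the focal parent (the parent whose meiosis
    is phased); ``parent_sex`` says which parent is focal.
    """

    table: pd.DataFrame

    REQUIRED = (
        "offspring",
        "sire",
        "dam",
        "grandsire",
        "parent_sex",
        "parent_age_months",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"pedigree missing columns: {missing}")
        sexes = set(self.table["parent_sex"].unique())
        if not sexes <= {"male", "female"}:
            raise ValueError(f"parent_sex must be male/female, got {sexes}")
        ages = self.table["parent_age_months"]
        if (ages.dropna() < 0).any():
            raise ValueError("parent ages must be >= 0")
        for _, row in self.table.iterrows():
            parent = row["sire"] if row["parent_sex"] == "male" else row["dam"]
            if row["offspring"] in (parent, row["grandsire"]):
                raise ValueError(
                    f"offspring {row['offspring']} listed as its own ancestor"
                )

    def __len__(self) -> int:
        return len(self.table)

    def focal_parent(self, row: pd.Series) -> str:
        return row["sire"] if row["parent_sex"] == "male" else row["dam"]


@dataclass
class EstimateRecord:
    """A fitted (nu, p) pair with uncertainty, for one scope."""

    scope: str  # "genome" | "chrom:<k>" | "group:<g>" | "parent:<id>"
    nu_hat: float
    p_hat: float
    se_nu: float | None
    se_p: float | None
    loglik: float
    n_meioses: int
    converged: bool = True

    def __post_init__(self) -> None:
        if self.converged and not self.nu_hat > 0:
            raise ValueError("nu_hat must be positive")
        if self.converged and not (0.0 <= self.p_hat <= 1.0):
            raise ValueError("p_hat must lie in [0, 1]")
        for se in (self.se_nu, self.se_p):
            if se is not None and np.isfinite(se) and se < 0:
                raise ValueError("standard errors must be >= 0")
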