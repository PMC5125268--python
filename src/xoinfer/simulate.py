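"""Synthetic meioses, trio genotypes and population-scale test data.

The generator produces data with exactly the structure the analysis
assumes: chiasmata from a stationary gamma renewal process (shape ``nu``,
rate ``2*q*nu``) thinned by 1/2 onto a chromatid, an independent Poisson
escape pathway at rate ``p`` per Morgan, Mendelian transmission through
three-generation families, and per-parent parameter rules (causal SNP on
``nu``, maternal-age rule on ``p``) for association and age-trend tests.

Founder haplotypes are drawn in linkage equilibrium; the point of the
markers is informativeness for phasing, not realistic LD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .core import (
    MISSING,
    ChromosomeMap,
    GenotypeTable,
    HSParameters,
    IntervalData,
    PedigreeTable,
)

__all__ = [
    "SimulatedMeiosis",
    "SimulationConfig",
    "SimulatedPopulation",
    "simulate_crossovers",
    "simulate_crossover_positions",
    "simulate_trio",
    "simulate_population",
    "uniform_marker_map",
]


@dataclass
class SimulatedMeiosis:
    """Latent chiasmata and realized crossovers on one chromosome."""

    chiasmata: np.ndarray  # latent interference-pathway chiasma positions
    positions: np.ndarray  # realized crossover positions, sorted
    pathways: np.ndarray  # per crossover: "interference" | "escape"
    length: float
    parent_id: str = "sim"
    parent_sex: str = "male"
    parent_age_months: float | None = None

    def interval_data(self) -> IntervalData:
        return IntervalData(tuple(self.positions), self.length)


def _stationary_chiasmata(
    nu: float, rate: float, length: float, n: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Chiasma positions for n meioses on [0, length].

    The first gap is drawn from the forward-recurrence distribution of the
    gamma renewal process (U times a length-biased Gamma(nu + 1, rate)
    gap), so the process is stationary from the chromosome start.
    """
    if length == 0.0 or rate == 0.0:
        return [np.empty(0) for _ in range(n)]
    mean_count = rate / (2.0 * nu) * length * 2.0  # = 2 q length
    cols = max(8, int(mean_count + 10.0 * np.sqrt(max(mean_count, 1.0)) + 10))
    first = rng.uniform(size=n) * rng.gamma(nu + 1.0, 1.0 / rate, size=n)
    out: list[np.ndarray] = [np.empty(0)] * n
    pending = np.arange(n)
    pos0 = first
    while pending.size:
        m = pending.size
        gaps = rng.gamma(nu, 1.0 / rate, size=(m, cols))
        cum = pos0[:, None] + np.concatenate(
            [np.zeros((m, 1)), np.cumsum(gaps, axis=1)], axis=1
        )
        done = cum[:, -1] > length
        for row in np.flatnonzero(done):
            c = cum[row]
            out[pending[row]] = c[c <= length]
        # rows that did not overflow the window get more columns (rare)
        pos0 = cum[~done, -1]
        pending = pending[~done]
    return out


def simulate_crossover_positions(
    params: HSParameters,
    length_morgans: float,
    n_meioses: int,
    rng: np.random.Generator,
) -> tuple[list[np.ndarray], list[np.ndarray], list[np.ndarray]]:
    """Vectorized batch simulation.

    Returns (chiasmata, crossover positions, pathway labels) per meiosis.
    Interference-pathway chiasmata are retained on the transmitted
    chromatid with probability 1/2; escape crossovers are a Poisson
    process with rate p per Morgan, simulated directly.
    """
    if length_morgans < 0:
        raise ValueError("chromosome length must be >= 0")
    nu, p, q = params.nu, params.p, params.q
    chias = _stationary_chiasmata(nu, 2.0 * q * nu, length_morgans, n_meioses, rng)
    n_escape = rng.poisson(p * length_morgans, size=n_meioses)
    positions: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    for i in range(n_meioses):
        keep = chias[i][rng.uniform(size=chias[i].size) < 0.5]
        esc = np.sort(rng.uniform(0.0, length_morgans, size=n_escape[i]))
        pos = np.concatenate([keep, esc])
        lab = np.concatenate(
            [
                np.full(keep.size, "interference"),
                np.full(esc.size, "escape"),
            ]
        )
        order = np.argsort(pos, kind="stable")
        positions.append(pos[order])
        labels.append(lab[order])
    return chias, positions, labels


def simulate_crossovers(
    params: HSParameters,
    length_morgans: float,
    seed: int | np.random.Generator,
) -> SimulatedMeiosis:
    """One chromosome of one meiosis under the interference-escape model."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    chias, pos, lab = simulate_crossover_positions(params, length_morgans, 1, rng)
    return SimulatedMeiosis(
        chiasmata=chias[0], positions=pos[0], pathways=lab[0], length=length_morgans
    )


def uniform_marker_map(
    chromosome: str,
    length_morgans: float,
    n_markers: int,
    bp_per_marker: int = 1_000_000,
    sex: str = "both",
) -> ChromosomeMap:
    """Evenly spaced markers spanning a chromosome of known genetic length."""
    if n_markers < 2:
        raise ValueError("need at least two markers")
    rate = length_morgans / (n_markers - 1)
    return ChromosomeMap(
        chromosome=str(chromosome),
        marker_ids=[f"chr{chromosome}_m{j}" for j in range(n_markers)],
        bp=np.arange(1, n_markers + 1, dtype=np.int64) * bp_per_marker,
        interval_rates=np.full(n_markers - 1, rate),
        sex=sex,
    )


def _apply_noise(
    dosages: np.ndarray, error_rate: float, missing_rate: float, rng
) -> np.ndarray:
    out = dosages.copy()
    if error_rate > 0:
        flip = rng.uniform(size=out.shape) < error_rate
        shift = rng.integers(1, 3, size=out.shape)  # move to one of the other codes
        out[flip] = (out[flip] + shift[flip]) % 3
    if missing_rate > 0:
        out[rng.uniform(size=out.shape) < missing_rate] = MISSING
    return out


def simulate_trio(
    meiosis: SimulatedMeiosis,
    chrom_map: ChromosomeMap,
    founder_freq: float | np.ndarray = 0.5,
    error_rate: float = 0.0,
    missing_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
    family_id: str = "fam0",
) -> tuple[GenotypeTable, np.ndarray]:
    """Genotypes for one three-generation family plus the truth origin track.

    Samples emitted: grandsire, focal parent, mate, offspring (ids prefixed
    by ``family_id``).  The offspring's focal haplotype follows one
    grandparental haplotype and switches origin exactly at the simulated
    crossover positions, mapped to marker intervals via the chromosome
    map.  The returned truth track holds, per marker, 1 where the focal
    haplotype is grandpaternal (from the grandsire) and 2 where it is
    grandmaternal.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    m = len(chrom_map.marker_ids)
    freqs = np.broadcast_to(np.asarray(founder_freq, dtype=float), (m,))
    cm = chrom_map.cum_cm
    span = cm[-1] / 100.0
    if meiosis.positions.size and meiosis.positions.max() > span + 1e-9:
        raise ValueError("crossover position outside the map's genetic span")

    def haplo() -> np.ndarray:
        return (rng.uniform(size=m) < freqs).astype(np.int8)

    gs_h = (haplo(), haplo())  # grandsire
    gd_h = (haplo(), haplo())  # grandam (ungenotyped)
    mate_h = (haplo(), haplo())
    # parent: paternal haplotype from the grandsire, maternal from the grandam
    parent_pat = gs_h[rng.integers(2)]
    parent_mat = gd_h[rng.integers(2)]

    # grandparental origin of the transmitted focal haplotype: switches at
    # each crossover; 1 = grandpaternal, 2 = grandmaternal
    marker_morgans = cm / 100.0
    n_switch = np.searchsorted(np.sort(meiosis.positions), marker_morgans, side="left")
    start = rng.integers(2)  # which grandparent the haplotype starts on
    origin = np.where((n_switch + start) % 2 == 0, 1, 2).astype(np.int8)
    focal = np.where(origin == 1, parent_pat, parent_mat).astype(np.int8)
    off_other = mate_h[rng.integers(2)]

    ids = [f"{family_id}_gs", f"{family_id}_parent", f"{family_id}_mate", f"{family_id}_off"]
    dos = np.vstack(
        [
            gs_h[0] + gs_h[1],
            parent_pat + parent_mat,
            mate_h[0] + mate_h[1],
            focal + off_other,
        ]
    ).astype(np.int8)
    dos = _apply_noise(dos, error_rate, missing_rate, rng)
    table = GenotypeTable(
        sample_ids=ids,
        marker_ids=list(chrom_map.marker_ids),
        dosages=dos,
        chromosomes=[chrom_map.chromosome] * m,
        positions_bp=chrom_map.bp,
    )
    return table, origin


@dataclass
class SimulationConfig:
    """Population-scale generator settings.

    Defaults emulate a dense-chip cattle half-sib design: many parents,
    tens of offspring each, one-Morgan-scale autosomes, biallelic SNPs in
    linkage equilibrium.  Per-parent interference follows
    ``nu = nu0 + beta_nu * dosage`` at the causal SNP; the escape fraction
    can decline with parent age through ``p_by_age``.
    """

    n_parents: int = 600
    n_offspring: int = 30
    parent_sex: str = "male"
    chrom_lengths: dict[str, float] = field(
        default_factory=lambda: {"1": 1.6, "2": 1.4, "3": 1.2, "4": 1.0, "5": 0.8}
    )
    nu0: float = 7.0
    p0: float = 0.05
    beta_nu: float = 0.0
    causal_snp: int | None = None  # column index into the GWAS panel
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    p_by_age: Callable[[float], float] | None = None
    age_range_months: tuple[float, float] = (24.0, 120.0)
    markers_per_chromosome: int = 0  # 0: no trio genotypes, truth intervals only
    error_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_parents < 1 or self.n_offspring < 1:
            raise ValueError("counts must be positive")
        if not all(length > 0 for length in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be > 0")
        for r in (self.error_rate, self.missing_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.causal_snp is not None and not (
            0 <= self.causal_snp < self.n_snps
        ):
            raise ValueError("causal_snp index outside the SNP panel")


@dataclass
class SimulatedPopulation:
    """Everything the pipeline consumes plus the generating truth."""

    parent_genotypes: GenotypeTable  # parents x GWAS SNP panel
    pedigree: PedigreeTable
    meioses: pd.DataFrame  # meiosis_id, parent_id, chromosome, length, positions
    parent_truth: pd.DataFrame  # parent_id, nu, p, age_months, causal_dosage
    family_genotypes: GenotypeTable | None = None  # trio genotypes, optional
    truth_origins: dict[str, dict[str, np.ndarray]] | None = None
    marker_maps: dict[str, ChromosomeMap] | None = None

    def intervals_by_parent(self) -> dict[str, list[IntervalData]]:
        out: dict[str, list[IntervalData]] = {}
        for row in self.meioses.itertuples():
            out.setdefault(row.parent_id, []).append(
                IntervalData(tuple(row.positions), row.length)
            )
        return out


def simulate_population(config: SimulationConfig) -> SimulatedPopulation:
    """Simulate parents, their GWAS SNP panel, and all offspring meioses."""
    rng = np.random.default_rng(config.seed)
    n, k = config.n_parents, config.n_snps
    parent_ids = [f"p{i:05d}" for i in range(n)]

    freqs = rng.uniform(*config.maf_range, size=k)
    dosages = rng.binomial(2, freqs[None, :], size=(n, k)).astype(np.int8)
    snp_ids = [f"snp{j:05d}" for j in range(k)]
    snp_chrom = [str(1 + (j * 29) // k) for j in range(k)]
    snp_bp = [1_000_000 * (j + 1) for j in range(k)]
    parent_geno = GenotypeTable(parent_ids, snp_ids, dosages, snp_chrom, snp_bp)

    ages = rng.uniform(*config.age_range_months, size=n)
    causal_dos = (
        dosages[:, config.causal_snp].astype(float)
        if config.causal_snp is not None
        else np.zeros(n)
    )
    nu_true = config.nu0 + config.beta_nu * causal_dos
    p_true = np.array(
        [
            config.p_by_age(a) if config.p_by_age is not None else config.p0
            for a in ages
        ]
    )
    if np.any(nu_true <= 0) or np.any((p_true < 0) | (p_true > 1)):
        raise ValueError("parameter rules produced invalid (nu, p)")

    ped_rows = []
    mei_rows = []
    for i, pid in enumerate(parent_ids):
        params = HSParameters(float(nu_true[i]), float(p_true[i]))
        for chrom, length in config.chrom_lengths.items():
            _, pos, _ = simulate_crossover_positions(
                params, length, config.n_offspring, rng
            )
            for j in range(config.n_offspring):
                mei_rows.append(
                    {
                        "meiosis_id": f"{pid}_o{j:03d}",
                        "parent_id": pid,
                        "parent_sex": config.parent_sex,
                        "parent_age_months": float(ages[i]),
                        "chromosome": chrom,
                        "length": length,
                        "positions": tuple(pos[j]),
                    }
                )
        for j in range(config.n_offspring):
            off = f"{pid}_o{j:03d}"
            ped_rows.append(
                {
                    "offspring": off,
                    "sire": pid if config.parent_sex == "male" else f"mate_{pid}",
                    "dam": pid if config.parent_sex == "female" else f"mate_{pid}",
                    "grandsire": f"gs_{pid}",
                    "parent_sex": config.parent_sex,
                    "parent_age_months": float(ages[i]),
                }
            )

    pop = SimulatedPopulation(
        parent_genotypes=parent_geno,
        pedigree=PedigreeTable(pd.DataFrame(ped_rows)),
        meioses=pd.DataFrame(mei_rows),
        parent_truth=pd.DataFrame(
            {
                "parent_id": parent_ids,
                "nu": nu_true,
                "p": p_true,
                "age_months": ages,
                "causal_dosage": causal_dos,
            }
        ),
    )
    if config.markers_per_chromosome >= 2:
        pop.marker_maps = {
            chrom: uniform_marker_map(chrom, length, config.markers_per_chromosome)
            for chrom, length in config.chrom_lengths.items()
        }
        pop.family_genotypes, pop.truth_origins = _family_genotypes(pop, config, rng)
    return pop


def _family_genotypes(
    pop: SimulatedPopulation, config: SimulationConfig, rng: np.random.Generator
) -> tuple[GenotypeTable, dict[str, dict[str, np.ndarray]]]:
    """Trio genotypes for every offspring over every chromosome map.

    One grandsire/grandam/mate per parent; each offspring's focal
    haplotype recombines the parent's two haplotypes at the simulated
    crossover positions.  Returns one combined table over all families
    and the truth origin tracks keyed by meiosis then chromosome.
    """
    assert pop.marker_maps is not None
    maps = pop.marker_maps
    by_parent: dict[str, pd.DataFrame] = dict(tuple(pop.meioses.groupby("parent_id")))
    m_per = {c: len(maps[c].marker_ids) for c in maps}
    chroms = list(maps)

    sample_ids: list[str] = []
    rows: list[np.ndarray] = []
    origins: dict[str, dict[str, np.ndarray]] = {}
    for pid, sub in by_parent.items():
        parent_pat: dict[str, np.ndarray] = {}
        parent_mat: dict[str, np.ndarray] = {}
        gs_dos: list[np.ndarray] = []
        parent_dos: list[np.ndarray] = []
        mate_dos: list[np.ndarray] = []
        mate_h: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for c in chroms:
            m = m_per[c]
            h = lambda: (rng.uniform(size=m) < 0.5).astype(np.int8)
            gs = (h(), h())
            gd = (h(), h())
            mate_h[c] = (h(), h())
            parent_pat[c] = gs[rng.integers(2)]
            parent_mat[c] = gd[rng.integers(2)]
            gs_dos.append(gs[0] + gs[1])
            parent_dos.append(parent_pat[c] + parent_mat[c])
            mate_dos.append(mate_h[c][0] + mate_h[c][1])
        sample_ids += [f"gs_{pid}", pid, f"mate_{pid}"]
        rows += [np.concatenate(gs_dos), np.concatenate(parent_dos), np.concatenate(mate_dos)]

        for mid, mei in sub.groupby("meiosis_id"):
            off_dos: list[np.ndarray] = []
            origins[mid] = {}
            for c in chroms:
                rec = mei[mei["chromosome"] == c].iloc[0]
                cmap = maps[c]
                marker_morgans = cmap.cum_cm / 100.0
                pos = np.sort(np.asarray(rec.positions))
                n_switch = np.searchsorted(pos, marker_morgans, side="left")
                start = rng.integers(2)
                origin = np.where((n_switch + start) % 2 == 0, 1, 2).astype(np.int8)
                focal = np.where(origin == 1, parent_pat[c], parent_mat[c])
                other = mate_h[c][rng.integers(2)]
                off_dos.append((focal + other).astype(np.int8))
                origins[mid][c] = origin
            sample_ids.append(mid)
            rows.append(np.concatenate(off_dos))

    dosages = _apply_noise(
        np.vstack(rows).astype(np.int8), config.error_rate, config.missing_rate, rng
    )
    marker_ids = [mid for c in chroms for mid in maps[c].marker_ids]
    chrom_col = [c for c in chroms for _ in maps[c].marker_ids]
    bp_col = [int(b) for c in chroms for b in maps[c].bp]
    table = GenotypeTable(sample_ids, marker_ids, dosages, chrom_col, bp_col)
    return table, origins
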