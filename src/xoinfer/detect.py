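"""Trio phasing and crossover detection.

Within a three-generation family (offspring, focal parent, grandsire of
the focal parent) the transmitted parental haplotype can be phased
deterministically at markers where the parent is heterozygous: the
transmitted allele follows from the offspring genotype (and the mate's,
when it settles an ambiguous heterozygous offspring), and a homozygous
grandsire then reveals which of the parent's two haplotypes carries it.
Crossovers appear as switches of grandparental origin between
consecutive informative markers.

Isolated origin runs supported by a single informative marker flanked on
both sides by the same origin are reverted to the surrounding origin
before calling switches; at dense-chip marker spacing such double
switches are overwhelmingly genotyping errors, and genuine double
crossovers within one inter-marker gap are unobservable anyway.
Meioses retaining more than three crossovers on any single chromosome
are discarded entirely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    MISSING,
    ChromosomeMap,
    CrossoverRecord,
    GenotypeTable,
    Meiosis,
    PedigreeTable,
)

logger = logging.getLogger(__name__)

UNINFORMATIVE, GRANDPATERNAL, GRANDMATERNAL = 0, 1, 2
MAX_CROSSOVERS_PER_CHROMOSOME = 3
MENDEL_FAMILY_THRESHOLD = 0.05

__all__ = [
    "OriginTrack",
    "FamilyExcluded",
    "phase_focal_haplotype",
    "detect_crossovers",
    "filter_meioses",
    "detect_all",
    "MAX_CROSSOVERS_PER_CHROMOSOME",
]


class FamilyExcluded(Exception):
    """Raised when a family exceeds the Mendelian-inconsistency threshold."""


@dataclass
class OriginTrack:
    """Per-marker grandparental origin of the focal transmitted haplotype."""

    chromosome: str
    marker_ids: list[str]
    bp: np.ndarray
    origins: np.ndarray  # int8: 0 uninformative, 1 grandpaternal, 2 grandmaternal
    n_mendel_errors: int = 0

    def informative(self) -> np.ndarray:
        return np.flatnonzero(self.origins != UNINFORMATIVE)


def phase_focal_haplotype(
    offspring: np.ndarray,
    parent: np.ndarray,
    grandsire: np.ndarray,
    chromosome: str,
    marker_ids: list[str],
    bp: np.ndarray,
    mate: np.ndarray | None = None,
) -> OriginTrack:
    """Deduce grandparental origin of the transmitted haplotype per marker.

    Arguments are dosage vectors (0/1/2, MISSING) over the chromosome's
    markers.  A marker is informative when the parent is heterozygous,
    the transmitted allele is identifiable, and the grandsire is
    homozygous.  Mendelian-inconsistent markers are set uninformative and
    counted.
    """
    o = np.asarray(offspring)
    p = np.asarray(parent)
    g = np.asarray(grandsire)
    m = np.asarray(mate) if mate is not None else None
    n = o.shape[0]
    origins = np.zeros(n, dtype=np.int8)

    present = (o != MISSING) & (p != MISSING) & (g != MISSING)
    mate_allele = np.full(n, -1, dtype=np.int8)
    if m is not None:
        mate_allele = np.where(m == 0, 0, np.where(m == 2, 1, -1)).astype(np.int8)
        mate_allele[m == MISSING] = -1

    # Mendelian checks on every present marker (family-level QC)
    mendel_bad = present & (((p == 0) & (o == 2)) | ((p == 2) & (o == 0)))
    if m is not None:
        mm = m != MISSING
        mendel_bad |= (
            (o != MISSING) & mm & (((m == 0) & (o == 2)) | ((m == 2) & (o == 0)))
        )
    n_mendel = int(mendel_bad.sum())

    # transmitted allele at parent-heterozygous markers
    het = present & (p == 1) & ~mendel_bad
    transmitted = np.full(n, -1, dtype=np.int8)
    transmitted[het & (o == 0)] = 0
    transmitted[het & (o == 2)] = 1
    amb = het & (o == 1) & (mate_allele >= 0)
    transmitted[amb] = 1 - mate_allele[amb]

    # grandsire homozygous -> the parent's grandpaternal haplotype allele
    gs_allele = np.where(g == 0, 0, np.where(g == 2, 1, -1)).astype(np.int8)
    ok = het & (transmitted >= 0) & (gs_allele >= 0)
    origins[ok & (transmitted == gs_allele)] = GRANDPATERNAL
    origins[ok & (transmitted != gs_allele)] = GRANDMATERNAL

    return OriginTrack(
        chromosome=str(chromosome),
        marker_ids=list(marker_ids),
        bp=np.asarray(bp, dtype=np.int64),
        origins=origins,
        n_mendel_errors=n_mendel,
    )


def _collapse_runs(
    origins: np.ndarray, idx: np.ndarray, min_run: int
) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encode origins at informative markers, reverting interior
    runs of <= min_run markers flanked by the same origin on both sides."""
    vals = origins[idx]
    while True:
        # run-length encode
        cut = np.flatnonzero(np.diff(vals) != 0) + 1
        starts = np.concatenate([[0], cut])
        ends = np.concatenate([cut, [len(vals)]])
        rvals = vals[starts]
        if len(rvals) < 3 or min_run < 1:
            break
        changed = False
        for r in range(1, len(rvals) - 1):
            if (
                ends[r] - starts[r] <= min_run
                and rvals[r - 1] == rvals[r + 1]
                and rvals[r] != rvals[r - 1]
            ):
                vals[starts[r] : ends[r]] = rvals[r - 1]
                changed = True
        if not changed:
            break
    return vals, idx


def detect_crossovers(
    track: OriginTrack,
    chrom_map: ChromosomeMap | None = None,
    meiosis_id: str = "meiosis",
    min_run: int = 1,
) -> list[CrossoverRecord]:
    """Call one crossover per origin switch between consecutive informative
    markers, after collapsing single-marker (<= min_run) interior flips.

    The genetic midpoint is the mean of the flanking markers' cM positions
    when a map is supplied, NaN otherwise.
    """
    idx = track.informative()
    if idx.size < 2:
        logger.warning(
            "chromosome %s: %d informative marker(s); no crossovers callable",
            track.chromosome,
            idx.size,
        )
        return []
    vals, idx = _collapse_runs(track.origins.copy(), idx, min_run)
    switches = np.flatnonzero(np.diff(vals) != 0)
    records = []
    if chrom_map is not None:
        cm = chrom_map.genetic_position_cm(track.bp.astype(float))
    for s in switches:
        li, ri = idx[s], idx[s + 1]
        mid = float((cm[li] + cm[ri]) / 2.0) if chrom_map is not None else float("nan")
        records.append(
            CrossoverRecord(
                meiosis_id=meiosis_id,
                chromosome=track.chromosome,
                left_marker=track.marker_ids[li],
                left_bp=int(track.bp[li]),
                right_marker=track.marker_ids[ri],
                right_bp=int(track.bp[ri]),
                midpoint_cm=mid,
            )
        )
    return records


def filter_meioses(meioses: list[Meiosis]) -> list[Meiosis]:
    """Drop any meiosis with more than three crossovers on one chromosome."""
    kept = [m for m in meioses if m.max_count() <= MAX_CROSSOVERS_PER_CHROMOSOME]
    n_dropped = len(meioses) - len(kept)
    if n_dropped:
        logger.info(
            "filtered %d meioses with >%d crossovers on a chromosome",
            n_dropped,
            MAX_CROSSOVERS_PER_CHROMOSOME,
        )
    return kept


def detect_all(
    genotypes: GenotypeTable,
    pedigree: PedigreeTable,
    maps: dict[str, ChromosomeMap] | None = None,
    min_run: int = 1,
    apply_filter: bool = True,
) -> tuple[list[Meiosis], pd.DataFrame]:
    """Run phasing + detection for every family in the pedigree.

    Returns the (optionally filtered) meioses and a per-family summary
    with crossover counts and exclusion reasons.  Families whose members
    are not all genotyped, or with >5% Mendelian-inconsistent markers,
    are excluded and logged.
    """
    chroms = genotypes.chromosome_labels()
    summaries = []
    meioses: list[Meiosis] = []
    for _, row in pedigree.table.iterrows():
        parent = pedigree.focal_parent(row)
        mate = row["dam"] if row["parent_sex"] == "male" else row["sire"]
        off, gs = row["offspring"], row["grandsire"]
        needed = [off, parent, gs]
        if not all(genotypes.has_sample(s) for s in needed):
            summaries.append(
                {"offspring": off, "parent": parent, "status": "missing_sample"}
            )
            continue
        mate_row = genotypes.sample_row(mate) if genotypes.has_sample(mate) else None
        mei = Meiosis(
            meiosis_id=f"{parent}:{off}",
            parent_id=str(parent),
            offspring_id=str(off),
            parent_sex=row["parent_sex"],
            parent_age_months=row["parent_age_months"],
        )
        n_mendel = 0
        n_checked = 0
        for c in chroms:
            mask = genotypes.marker_mask(c)
            track = phase_focal_haplotype(
                genotypes.sample_row(off)[mask],
                genotypes.sample_row(parent)[mask],
                genotypes.sample_row(gs)[mask],
                chromosome=c,
                marker_ids=[
                    genotypes.marker_ids[j] for j in np.flatnonzero(mask)
                ],
                bp=genotypes.positions_bp[mask],
                mate=mate_row[mask] if mate_row is not None else None,
            )
            n_mendel += track.n_mendel_errors
            n_checked += int(mask.sum())
            mei.crossovers[c] = detect_crossovers(
                track,
                chrom_map=maps.get(c) if maps else None,
                meiosis_id=mei.meiosis_id,
                min_run=min_run,
            )
        if n_checked and n_mendel / n_checked > MENDEL_FAMILY_THRESHOLD:
            logger.warning(
                "family %s excluded: %.1f%% Mendelian-inconsistent markers",
                mei.meiosis_id,
                100.0 * n_mendel / n_checked,
            )
            summaries.append(
                {"offspring": off, "parent": parent, "status": "mendel_excluded"}
            )
            continue
        summaries.append(
            {
                "offspring": off,
                "parent": parent,
                "status": "ok",
                "n_crossovers": sum(len(v) for v in mei.crossovers.values()),
                "max_per_chromosome": mei.max_count(),
            }
        )
        meioses.append(mei)
    if apply_filter:
        meioses = filter_meioses(meioses)
    kept_ids = {m.meiosis_id for m in meioses}
    summary = pd.DataFrame(summaries)
    if len(summary) and "status" in summary:
        ok = summary["status"] == "ok"
        summary.loc[ok, "status"] = [
            "ok" if f"{p}:{o}" in kept_ids else "count_filtered"
            for p, o in zip(summary.loc[ok, "parent"], summary.loc[ok, "offspring"])
        ]
    return meioses, summary
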