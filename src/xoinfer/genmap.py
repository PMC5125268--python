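"""Sex-specific genetic maps from detected crossovers.

The recombination fraction between adjacent SNPs, estimated as observed
crossovers divided by informative meioses, is used directly as genetic
distance (cM = 100 x rate).  A crossover localized to a flanking-marker
pair that spans several adjacent marker intervals contributes
fractionally to each, proportional to physical (bp) length — unbiased
under a uniform prior on the true position within the interval.
"""

from __future__ import annotations

import logging

import numpy as np

from .core import ChromosomeMap, CrossoverRecord, IntervalData, Meiosis

logger = logging.getLogger(__name__)

RATE_CAP = 0.5

__all__ = ["build_map", "build_maps", "to_genetic_intervals"]


def build_map(
    crossovers: list[CrossoverRecord],
    n_meioses: int,
    marker_ids: list[str],
    marker_bp: np.ndarray,
    chromosome: str,
    sex: str = "both",
) -> ChromosomeMap:
    """Per-interval recombination rates for one chromosome and one sex."""
    if n_meioses < 1:
        raise ValueError("need at least one meiosis")
    marker_bp = np.asarray(marker_bp, dtype=np.int64)
    index = {m: j for j, m in enumerate(marker_ids)}
    counts = np.zeros(max(len(marker_ids) - 1, 0))
    for rec in crossovers:
        if rec.chromosome != str(chromosome):
            continue
        if rec.left_marker not in index or rec.right_marker not in index:
            raise ValueError(
                f"crossover references unknown markers "
                f"{rec.left_marker}/{rec.right_marker}"
            )
        li, ri = index[rec.left_marker], index[rec.right_marker]
        span = float(marker_bp[ri] - marker_bp[li])
        # fractional allocation over the marker intervals the flanking pair spans
        seg = np.diff(marker_bp[li : ri + 1]).astype(float)
        counts[li:ri] += seg / span
    rates = counts / n_meioses
    n_capped = int(np.sum(rates > RATE_CAP))
    if n_capped:
        logger.warning(
            "chromosome %s: capped %d interval rate(s) at %.1f",
            chromosome,
            n_capped,
            RATE_CAP,
        )
        rates = np.minimum(rates, RATE_CAP)
    return ChromosomeMap(
        chromosome=str(chromosome),
        marker_ids=list(marker_ids),
        bp=marker_bp,
        interval_rates=rates,
        sex=sex,
    )


def build_maps(
    meioses: list[Meiosis],
    marker_ids_by_chrom: dict[str, list[str]],
    marker_bp_by_chrom: dict[str, np.ndarray],
    sex: str,
) -> dict[str, ChromosomeMap]:
    """One map per chromosome from the given sex's meioses."""
    mine = [m for m in meioses if m.parent_sex == sex]
    if not mine:
        raise ValueError(f"no meioses of sex {sex!r}")
    maps = {}
    for chrom, ids in marker_ids_by_chrom.items():
        recs = [r for m in mine for r in m.crossovers.get(chrom, [])]
        maps[chrom] = build_map(
            recs, len(mine), ids, marker_bp_by_chrom[chrom], chrom, sex=sex
        )
    return maps


def to_genetic_intervals(
    meiosis: Meiosis, maps: dict[str, ChromosomeMap]
) -> dict[str, IntervalData]:
    """Crossover positions in Morgans per chromosome, zero-crossover ones
    included (they still inform the likelihood through censoring)."""
    out: dict[str, IntervalData] = {}
    for chrom, cmap in maps.items():
        recs = sorted(
            meiosis.crossovers.get(chrom, []), key=lambda r: (r.left_bp, r.right_bp)
        )
        length = cmap.length_cm / 100.0
        positions = []
        for r in recs:
            left = cmap.genetic_position_cm(float(r.left_bp))
            right = cmap.genetic_position_cm(float(r.right_bp))
            positions.append(float((left + right) / 2.0) / 100.0)
        # records flank disjoint informative intervals, so positions are
        # nondecreasing; drop exact ties arising from zero-rate intervals
        uniq = []
        for x in positions:
            if not uniq or x > uniq[-1]:
                uniq.append(min(x, length))
        out[chrom] = IntervalData(tuple(uniq), length)
    return out
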