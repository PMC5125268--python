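"""Shared truth-projection oracle for detection tests.

A planted crossover is only observable at the resolution of the phased
informative-marker grid: between two consecutive informative markers,
detection can see a switch only when an odd number of true crossovers
fell in that genetic window.  These helpers project simulated truth
positions onto that grid and score detected records against it.
"""

from __future__ import annotations

import numpy as np

from xoinfer.detect import phase_focal_haplotype


def expected_switch_pairs(origins, bp, truth_positions, cmap):
    """Pairs of informative marker indices whose window holds an odd
    number of true crossovers (the observable switches)."""
    idx = np.flatnonzero(origins != 0)
    cm = cmap.cum_cm / 100.0
    pairs = set()
    for a, b in zip(idx, idx[1:]):
        k = int(np.sum((truth_positions > cm[a]) & (truth_positions <= cm[b])))
        if k % 2 == 1:
            pairs.add((int(a), int(b)))
    return pairs


def evaluate_detection(pop, meioses):
    """Score detected crossovers against simulated truth.

    Returns (n_expected, n_recovered, n_false, n_meioses): expected =
    observable switches on each meiosis' informative grid; recovered =
    detected records matching an expected switch window (odd truth
    parity); false = detected records whose window holds an even number
    of true crossovers.
    """
    geno = pop.family_genotypes
    maps = pop.marker_maps
    truth = pop.meioses.set_index(["meiosis_id", "chromosome"])
    n_expected = n_recovered = n_false = 0
    marker_index = {m: j for j, m in enumerate(geno.marker_ids)}
    for mei in meioses:
        off = mei.offspring_id
        parent = mei.parent_id
        for chrom, recs in mei.crossovers.items():
            cmap = maps[chrom]
            mask = geno.marker_mask(chrom)
            track = phase_focal_haplotype(
                geno.sample_row(off)[mask],
                geno.sample_row(parent)[mask],
                geno.sample_row(f"gs_{parent}")[mask],
                chromosome=chrom,
                marker_ids=[geno.marker_ids[j] for j in np.flatnonzero(mask)],
                bp=geno.positions_bp[mask],
                mate=geno.sample_row(f"mate_{parent}")[mask],
            )
            pos = np.asarray(truth.loc[(off, chrom), "positions"])
            expected = expected_switch_pairs(track.origins, track.bp, pos, cmap)
            n_expected += len(expected)
            cm = cmap.cum_cm / 100.0
            local = {m: j for j, m in enumerate(track.marker_ids)}
            for r in recs:
                li, ri = local[r.left_marker], local[r.right_marker]
                k = int(np.sum((pos > cm[li]) & (pos <= cm[ri])))
                if k % 2 == 1:
                    n_recovered += 1
                else:
                    n_false += 1
    return n_expected, n_recovered, n_false, len(meioses)
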