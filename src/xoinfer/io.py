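"""Readers and writers for the pipeline's tabular formats.

Formats are deliberately plain text: a wide genotype TSV (samples x
markers, dosage-coded) with a sidecar marker map, PLINK-style .ped/.map
text, a BED-like crossover TSV, pedigree/interval/map/estimate TSVs, and
a flat key=value config.  Chromosome X is dropped on genotype input
because the analysis is autosome-only.  All writer/reader pairs
round-trip exactly.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    MISSING,
    ChromosomeMap,
    CrossoverRecord,
    EstimateRecord,
    GenotypeTable,
    IntervalData,
    PedigreeTable,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_pedigree",
    "write_pedigree",
    "read_crossovers",
    "write_crossovers",
    "read_intervals",
    "write_intervals",
    "read_maps",
    "write_maps",
    "read_estimates",
    "write_estimates",
    "read_config",
    "setup_logging",
]


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


def _drop_x(
    marker_ids: list[str],
    chroms: list[str],
    bps: list[int],
    dosages: np.ndarray,
) -> tuple[list[str], list[str], list[int], np.ndarray]:
    keep = [j for j, c in enumerate(chroms) if c.upper() != "X"]
    n_dropped = len(chroms) - len(keep)
    if n_dropped:
        logger.info("dropped %d chromosome X marker(s)", n_dropped)
    return (
        [marker_ids[j] for j in keep],
        [chroms[j] for j in keep],
        [bps[j] for j in keep],
        dosages[:, keep],
    )


def _read_marker_map(map_path: Path) -> tuple[list[str], list[str], list[int]]:
    ids: list[str] = []
    chroms: list[str] = []
    bps: list[int] = []
    with open(map_path) as fh:
        header = fh.readline()
        if not header.startswith("marker"):
            raise ParseError(f"{map_path}:1: expected header starting with 'marker'")
        for ln, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ParseError(f"{map_path}:{ln}: expected 3 columns")
            ids.append(parts[0])
            chroms.append(parts[1])
            try:
                bps.append(int(parts[2]))
            except ValueError:
                raise ParseError(f"{map_path}:{ln}: bad bp position {parts[2]!r}")
    return ids, chroms, bps


def _read_tsv_genotypes(path: Path, map_path: Path) -> GenotypeTable:
    ids, chroms, bps = _read_marker_map(map_path)
    sample_ids: list[str] = []
    rows: list[list[int]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "sample_id":
            raise ParseError(f"{path}:1: expected 'sample_id' as first column")
        markers = header[1:]
        if markers != ids:
            raise ParseError(
                f"{path}:1: marker columns do not match the map file"
            )
        for ln, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(markers) + 1:
                raise ParseError(f"{path}:{ln}: expected {len(markers)+1} columns")
            sample_ids.append(parts[0])
            row = []
            for v in parts[1:]:
                if v == "NA":
                    row.append(MISSING)
                elif v in ("0", "1", "2"):
                    row.append(int(v))
                else:
                    raise ParseError(f"{path}:{ln}: invalid genotype code {v!r}")
            rows.append(row)
    dosages = np.asarray(rows, dtype=np.int8)
    ids, chroms, bps, dosages = _drop_x(ids, chroms, bps, dosages)
    return GenotypeTable(sample_ids, ids, dosages, chroms, bps)


def _read_plink_genotypes(path: Path) -> GenotypeTable:
    """PLINK-style text: <prefix>.ped with alleles coded 1/2 (0 0 missing)
    and <prefix>.map with chrom, marker, cM, bp columns."""
    prefix = path.with_suffix("") if path.suffix == ".ped" else path
    ped, mp = prefix.with_suffix(".ped"), prefix.with_suffix(".map")
    ids, chroms, bps = [], [], []
    with open(mp) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) != 4:
                raise ParseError(f"{mp}:{ln}: expected 4 columns")
            chroms.append(parts[0])
            ids.append(parts[1])
            bps.append(int(parts[3]))
    sample_ids, rows = [], []
    with open(ped) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) != 6 + 2 * len(ids):
                raise ParseError(
                    f"{ped}:{ln}: expected {6 + 2*len(ids)} fields, got {len(parts)}"
                )
            sample_ids.append(parts[1])
            alleles = parts[6:]
            row = []
            for j in range(len(ids)):
                a, b = alleles[2 * j], alleles[2 * j + 1]
                if a == "0" or b == "0":
                    row.append(MISSING)
                elif a in "12" and b in "12":
                    row.append((a == "2") + (b == "2"))
                else:
                    raise ParseError(f"{ped}:{ln}: invalid allele pair {a!r}/{b!r}")
            rows.append(row)
    dosages = np.asarray(rows, dtype=np.int8)
    ids, chroms, bps, dosages = _drop_x(ids, chroms, bps, dosages)
    return GenotypeTable(sample_ids, ids, dosages, chroms, bps)


def read_genotypes(
    path: str | Path, format_name: str = "tsv", map_path: str | Path | None = None
) -> GenotypeTable:
    """Read a genotype file; chromosome X markers are dropped and logged.

    ``format_name`` is "tsv" (wide dosage TSV + marker-map sidecar,
    defaulting to <stem>.map) or "ped" (PLINK-style text).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format_name == "tsv":
        mp = Path(map_path) if map_path else path.with_suffix(".map")
        return _read_tsv_genotypes(path, mp)
    if format_name == "ped":
        return _read_plink_genotypes(path)
    raise ValueError(f"unsupported genotype format {format_name!r}")


def write_genotypes(
    table: GenotypeTable, path: str | Path, map_path: str | Path | None = None
) -> None:
    path = Path(path)
    mp = Path(map_path) if map_path else path.with_suffix(".map")
    with open(mp, "w") as fh:
        fh.write("marker\tchromosome\tbp\n")
        for m, c, b in zip(table.marker_ids, table.chromosomes, table.positions_bp):
            fh.write(f"{m}\t{c}\t{int(b)}\n")
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(table.marker_ids) + "\n")
        for i, s in enumerate(table.sample_ids):
            codes = [
                "NA" if d == MISSING else str(int(d)) for d in table.dosages[i]
            ]
            fh.write(s + "\t" + "\t".join(codes) + "\n")


PEDIGREE_COLUMNS = list(PedigreeTable.REQUIRED)


def read_pedigree(path: str | Path) -> PedigreeTable:
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in PEDIGREE_COLUMNS[:4]})
    df["parent_age_months"] = pd.to_numeric(df["parent_age_months"], errors="coerce")
    return PedigreeTable(df)


def write_pedigree(ped: PedigreeTable, path: str | Path) -> None:
    ped.table.to_csv(path, sep="\t", index=False, na_rep="NA")


_XO_HEADER = "chrom\tstart\tend\tmeiosis_id\tmidpoint_cm\tleft_marker\tright_marker\n"


def write_crossovers(records: list[CrossoverRecord], path: str | Path) -> None:
    """BED-like TSV: half-open [left_bp - 1, right_bp) interval per event."""
    with open(path, "w") as fh:
        fh.write(_XO_HEADER)
        for r in records:
            mid = "NA" if np.isnan(r.midpoint_cm) else repr(r.midpoint_cm)
            fh.write(
                f"{r.chromosome}\t{r.left_bp - 1}\t{r.right_bp}\t{r.meiosis_id}\t"
                f"{mid}\t{r.left_marker}\t{r.right_marker}\n"
            )


def read_crossovers(path: str | Path) -> list[CrossoverRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline()
        if header != _XO_HEADER:
            raise ParseError(f"{path}:1: unexpected crossover file header")
        for ln, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 7:
                raise ParseError(f"{path}:{ln}: expected 7 columns")
            chrom, start, end, mid_id, mid_cm, lm, rm = parts
            records.append(
                CrossoverRecord(
                    meiosis_id=mid_id,
                    chromosome=chrom,
                    left_marker=lm,
                    left_bp=int(start) + 1,
                    right_marker=rm,
                    right_bp=int(end),
                    midpoint_cm=float("nan") if mid_cm == "NA" else float(mid_cm),
                )
            )
    return records


def write_intervals(
    intervals: list[tuple[str, str, IntervalData]], path: str | Path
) -> None:
    """TSV of (meiosis id, chromosome, length in Morgans, positions)."""
    with open(path, "w") as fh:
        fh.write("meiosis_id\tchromosome\tlength_morgans\tpositions\n")
        for mid, chrom, iv in intervals:
            pos = ",".join(repr(x) for x in iv.positions) if iv.positions else "."
            fh.write(f"{mid}\t{chrom}\t{iv.length!r}\t{pos}\n")


def read_intervals(path: str | Path) -> list[tuple[str, str, IntervalData]]:
    out = []
    with open(path) as fh:
        fh.readline()
        for ln, line in enumerate(fh, start=2):
            mid, chrom, length, pos = line.rstrip("\n").split("\t")
            positions = (
                () if pos == "." else tuple(float(x) for x in pos.split(","))
            )
            out.append((mid, chrom, IntervalData(positions, float(length))))
    return out


def write_maps(maps: dict[str, ChromosomeMap], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chromosome\tsex\tmarker\tbp\tinterval_rate\tcum_cm\n")
        for chrom, m in maps.items():
            cum = m.cum_cm
            for j, (mid, bp) in enumerate(zip(m.marker_ids, m.bp)):
                rate = repr(float(m.interval_rates[j])) if j < len(m.interval_rates) else "NA"
                fh.write(
                    f"{m.chromosome}\t{m.sex}\t{mid}\t{int(bp)}\t{rate}\t{cum[j]!r}\n"
                )


def read_maps(path: str | Path) -> dict[str, ChromosomeMap]:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "marker": str})
    maps = {}
    for chrom, sub in df.groupby("chromosome", sort=False):
        rates = sub["interval_rate"].to_numpy(dtype=float)[:-1]
        maps[str(chrom)] = ChromosomeMap(
            chromosome=str(chrom),
            marker_ids=sub["marker"].tolist(),
            bp=sub["bp"].to_numpy(dtype=np.int64),
            interval_rates=rates,
            sex=str(sub["sex"].iloc[0]),
        )
    return maps


_EST_COLS = [
    "scope", "nu_hat", "p_hat", "se_nu", "se_p", "loglik", "n_meioses", "converged",
]


def write_estimates(records: list[EstimateRecord], path: str | Path) -> None:
    pd.DataFrame([vars(r) for r in records])[_EST_COLS].to_csv(
        path, sep="\t", index=False, na_rep="NA"
    )


def read_estimates(path: str | Path) -> list[EstimateRecord]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        out.append(
            EstimateRecord(
                scope=str(r["scope"]),
                nu_hat=float(r["nu_hat"]),
                p_hat=float(r["p_hat"]),
                se_nu=None if pd.isna(r["se_nu"]) else float(r["se_nu"]),
                se_p=None if pd.isna(r["se_p"]) else float(r["se_p"]),
                loglik=float(r["loglik"]),
                n_meioses=int(r["n_meioses"]),
                converged=bool(r["converged"]),
            )
        )
    return out


def read_config(path: str | Path) -> dict[str, str]:
    """Flat key=value file; '#' starts a comment."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParseError(f"{path}:{ln}: expected key=value")
            key, val = line.split("=", 1)
            out[key.strip()] = val.strip()
    return out


def setup_logging(log_path: str | Path | None = None, level: int = logging.INFO) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if log_path is not None:
        handlers.append(logging.FileHandler(log_path))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
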