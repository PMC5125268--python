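"""Association scans for crossover-interference phenotypes.

Per-parent phenotypes (the fitted interference parameter nu, the escape
fraction p, or the mean relative inter-crossover distance RCO) are
tested against SNPs with the linear mixed model

    y = X b + Z a + e,      a ~ N(0, G sigma_a^2),
                            Var(e_i) = w_i sigma_e^2,

where G is a VanRaden genomic relationship matrix and the per-individual
weights w_i are the squared standard errors from the per-parent
likelihood fits (the per-parent phenotype is itself an estimate, so its
sampling variance enters the residual).  Variance components are
estimated once by REML on the null (no-SNP) model through a single
eigendecomposition; each SNP is then tested by generalized least squares
with a Wald test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .core import ChromosomeMap, GenotypeTable, Meiosis

logger = logging.getLogger(__name__)

__all__ = [
    "bonferroni_threshold",
    "compute_rco",
    "vanraden_grm",
    "phenotypes_from_estimates",
    "gwas_scan",
    "conditional_scan",
    "meta_scan",
]


def phenotypes_from_estimates(records, parameter: str = "nu") -> pd.DataFrame:
    """Phenotype table (parent_id, value, residual_variance) from per-parent fits.

    The residual variance is the squared SE of the chosen parameter;
    parents whose Hessian-based SE is unavailable (boundary fits) get the
    cohort median so they stay in the scan rather than being dropped.
    """
    if parameter not in ("nu", "p"):
        raise ValueError("parameter must be 'nu' or 'p'")
    rows = []
    for r in records:
        se = r.se_nu if parameter == "nu" else r.se_p
        rows.append(
            {
                "parent_id": r.scope.split(":", 1)[1],
                "value": r.nu_hat if parameter == "nu" else r.p_hat,
                "residual_variance": se**2 if se is not None and np.isfinite(se) else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    med = df["residual_variance"].median()
    if np.isfinite(med) and med > 0:
        df["residual_variance"] = df["residual_variance"].fillna(med)
    else:
        df = df.drop(columns=["residual_variance"])
    return df


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Genome-wide significance level alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def compute_rco(
    meioses: list[Meiosis], maps: dict[str, ChromosomeMap]
) -> pd.Series:
    """Mean relative inter-crossover distance (RCO) per parent.

    Each inter-crossover distance on a chromosome is standardized by that
    chromosome's map length (cM / cM); a progeny's RCO averages these
    over all autosomes, and the parent's phenotype averages over progeny.
    Parents without any multi-crossover meiosis get no phenotype.
    """
    per_parent: dict[str, list[float]] = {}
    for mei in meioses:
        vals = []
        for chrom, recs in mei.crossovers.items():
            if len(recs) < 2 or chrom not in maps:
                continue
            length_cm = maps[chrom].length_cm
            if length_cm <= 0:
                continue
            mids = sorted(r.midpoint_cm for r in recs)
            vals.extend(float(b - a) / length_cm for a, b in zip(mids, mids[1:]))
        if vals:
            per_parent.setdefault(mei.parent_id, []).append(float(np.mean(vals)))
    return pd.Series(
        {p: float(np.mean(v)) for p, v in per_parent.items()}, name="rco", dtype=float
    )


def vanraden_grm(dosages: np.ndarray) -> np.ndarray:
    """Centered/scaled cross-product genomic relationship matrix."""
    d = np.asarray(dosages, dtype=float)
    freq = np.nanmean(np.where(d < 0, np.nan, d), axis=0) / 2.0
    d = np.where(d < 0, 2.0 * freq[None, :], d)  # mean-impute missing
    w = d - 2.0 * freq[None, :]
    denom = 2.0 * np.sum(freq * (1.0 - freq))
    if denom <= 0:
        raise ValueError("all SNPs monomorphic; GRM undefined")
    return w @ w.T / denom


class _EigenLMM:
    """Null-model REML machinery shared across all SNPs of a scan."""

    def __init__(self, y: np.ndarray, x_null: np.ndarray, grm: np.ndarray, weights: np.ndarray):
        self.sqrt_w = np.sqrt(weights)
        b = grm / self.sqrt_w[:, None] / self.sqrt_w[None, :]
        lam, u = np.linalg.eigh(b)
        self.lam = np.maximum(lam, 0.0)
        self.u = u
        self.y = u.T @ (y / self.sqrt_w)
        self.x0 = u.T @ (x_null / self.sqrt_w[:, None])
        self.delta = self._reml_delta()
        self.v = self.delta * self.lam + 1.0  # Var(y_i) / sigma_e^2 (rotated)
        self.sigma_e2 = self._profile_sigma_e2(self.x0)

    def _neg_reml(self, log_delta: float) -> float:
        v = np.exp(log_delta) * self.lam + 1.0
        xtvx = self.x0.T @ (self.x0 / v[:, None])
        beta = np.linalg.solve(xtvx, self.x0.T @ (self.y / v))
        r = self.y - self.x0 @ beta
        n, k = len(self.y), self.x0.shape[1]
        s2 = float(r @ (r / v)) / (n - k)
        _, logdet_xtvx = np.linalg.slogdet(xtvx)
        return 0.5 * (
            (n - k) * np.log(s2) + np.sum(np.log(v)) + logdet_xtvx + (n - k)
        )

    def _reml_delta(self) -> float:
        res = minimize_scalar(
            self._neg_reml, bounds=(-10.0, 10.0), method="bounded"
        )
        return float(np.exp(res.x))

    def _profile_sigma_e2(self, x: np.ndarray) -> float:
        xtvx = x.T @ (x / self.v[:, None])
        beta = np.linalg.solve(xtvx, x.T @ (self.y / self.v))
        r = self.y - x @ beta
        return float(r @ (r / self.v)) / (len(self.y) - x.shape[1])

    def rotate(self, col: np.ndarray) -> np.ndarray:
        return self.u.T @ (col / self.sqrt_w)

    def wald(self, x: np.ndarray) -> tuple[float, float, float]:
        """GLS fit with the tested SNP as the last column of x (rotated).

        The variance ratio delta is fixed at its null-model REML value;
        the residual scale is re-profiled under the SNP model so the Wald
        test reduces exactly to OLS when the covariance is proportional
        to the identity.  Returns (beta, se, p)."""
        xtvx = x.T @ (x / self.v[:, None])
        try:
            cov_unit = np.linalg.inv(xtvx)
        except np.linalg.LinAlgError:
            return np.nan, np.nan, np.nan
        beta = cov_unit @ (x.T @ (self.y / self.v))
        r = self.y - x @ beta
        s2 = float(r @ (r / self.v)) / (len(self.y) - x.shape[1])
        cov = cov_unit * s2
        se = float(np.sqrt(max(cov[-1, -1], 0.0)))
        if se == 0.0 or not np.isfinite(se):
            return float(beta[-1]), np.nan, np.nan
        z2 = (float(beta[-1]) / se) ** 2
        p = float(chi2.sf(z2, 1))
        return float(beta[-1]), se, max(p, np.finfo(float).tiny)


def _prepare(
    phenotypes: pd.DataFrame,
    genotypes: GenotypeTable,
    covariates: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[int], np.ndarray]:
    genotyped = phenotypes["parent_id"].map(genotypes.has_sample).to_numpy(bool)
    if not genotyped.all():
        logger.info("%d phenotyped parents lack genotypes", int((~genotyped).sum()))
    y_all = phenotypes["value"].to_numpy(dtype=float)
    keep = genotyped & np.isfinite(y_all)
    ids = phenotypes.loc[keep, "parent_id"].tolist()
    y = y_all[keep]
    if "residual_variance" in phenotypes and phenotypes["residual_variance"].notna().all():
        weights = phenotypes.loc[keep, "residual_variance"].to_numpy(dtype=float)
        if np.any(weights <= 0):
            raise ValueError("residual variances must be > 0")
    else:
        weights = np.ones(len(ids))
    dos = np.vstack([genotypes.sample_row(s) for s in ids]).astype(float)
    x_null = np.ones((len(ids), 1))
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != len(phenotypes):
            cov = cov.T
        cov = cov[keep]
        if np.any(np.ptp(cov, axis=0) == 0):
            raise ValueError("covariate is constant (collinear with intercept)")
        x_null = np.hstack([x_null, cov])
    return y, dos, weights, keep, x_null


def gwas_scan(
    phenotypes: pd.DataFrame,
    genotypes: GenotypeTable,
    kinship: np.ndarray | None = None,
    maf: float = 0.01,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Single-SNP mixed-model scan.

    ``phenotypes`` needs columns parent_id, value and optionally
    residual_variance (the squared SE of the per-parent fit).  Returns
    one row per tested SNP: snp, chromosome, bp, freq, beta, se, p.
    """
    y, dos, weights, _, x_null = _prepare(phenotypes, genotypes, covariates)
    if len(y) < 3:
        raise ValueError("too few phenotyped, genotyped parents")
    if np.ptp(y) == 0:
        logger.warning("constant phenotype; nothing to test")
        return pd.DataFrame(
            columns=["snp", "chromosome", "bp", "freq", "beta", "se", "p"]
        )
    if kinship is None:
        kinship = vanraden_grm(dos)
    lmm = _EigenLMM(y, x_null, kinship, weights)

    # rotate all SNP columns at once; mean-impute missing dosages
    freq = np.nanmean(np.where(dos < 0, np.nan, dos), axis=0) / 2.0
    dos = np.where(dos < 0, 2.0 * freq[None, :], dos)
    rotated = lmm.u.T @ (dos / lmm.sqrt_w[:, None])
    x0r = np.column_stack([lmm.rotate(x_null[:, j]) for j in range(x_null.shape[1])])

    rows = []
    for j in range(dos.shape[1]):
        fj = freq[j]
        if not np.isfinite(fj) or min(fj, 1.0 - fj) < maf or np.ptp(dos[:, j]) == 0:
            continue
        beta, se, p = lmm.wald(np.column_stack([x0r, rotated[:, j]]))
        if not np.isfinite(p):
            logger.debug("SNP %s skipped (singular design)", genotypes.marker_ids[j])
            continue
        rows.append(
            {
                "snp": genotypes.marker_ids[j],
                "chromosome": genotypes.chromosomes[j],
                "bp": int(genotypes.positions_bp[j]),
                "freq": float(fj),
                "beta": beta,
                "se": se,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def conditional_scan(
    phenotypes: pd.DataFrame,
    genotypes: GenotypeTable,
    recombination_rate: pd.Series,
    kinship: np.ndarray | None = None,
    maf: float = 0.01,
) -> pd.DataFrame:
    """Scan with the parent's recombination rate as a fixed covariate.

    ``recombination_rate`` is indexed by parent id (mean crossovers per
    meiosis).  An all-zero covariate is treated as absent, so results
    then equal the unconditional scan.
    """
    cov = recombination_rate.reindex(phenotypes["parent_id"]).to_numpy(dtype=float)
    if np.all(cov == 0):
        return gwas_scan(phenotypes, genotypes, kinship=kinship, maf=maf)
    return gwas_scan(
        phenotypes, genotypes, kinship=kinship, maf=maf, covariates=cov[:, None]
    )


def meta_scan(
    phenotypes_a: pd.DataFrame,
    genotypes_a: GenotypeTable,
    phenotypes_b: pd.DataFrame,
    genotypes_b: GenotypeTable,
    maf: float = 0.01,
) -> pd.DataFrame:
    """Pooled two-cohort scan restricted to the shared SNP set.

    Individuals are combined into one model with cohort as a fixed
    covariate; an empty second cohort degenerates to the single-cohort
    scan.
    """
    if len(phenotypes_b) == 0:
        return gwas_scan(phenotypes_a, genotypes_a, maf=maf)
    if len(phenotypes_a) == 0:
        return gwas_scan(phenotypes_b, genotypes_b, maf=maf)
    shared = [m for m in genotypes_a.marker_ids if m in set(genotypes_b.marker_ids)]
    if not shared:
        raise ValueError("cohorts share no SNPs")

    def subset(g: GenotypeTable, ids: list[str]) -> np.ndarray:
        col = {m: j for j, m in enumerate(g.marker_ids)}
        take = [col[m] for m in shared]
        return g.dosages[:, take]

    da = subset(genotypes_a, shared)
    db = subset(genotypes_b, shared)
    ja = {m: j for j, m in enumerate(genotypes_a.marker_ids)}
    chroms = [genotypes_a.chromosomes[ja[m]] for m in shared]
    bps = [int(genotypes_a.positions_bp[ja[m]]) for m in shared]
    merged = GenotypeTable(
        list(genotypes_a.sample_ids) + list(genotypes_b.sample_ids),
        shared,
        np.vstack([da, db]),
        chroms,
        bps,
    )
    pheno = pd.concat([phenotypes_a, phenotypes_b], ignore_index=True)
    cohort = np.concatenate(
        [np.zeros(len(phenotypes_a)), np.ones(len(phenotypes_b))]
    )
    return gwas_scan(pheno, merged, maf=maf, covariates=cohort[:, None])
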