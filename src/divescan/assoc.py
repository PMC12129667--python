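"""Stage two: covariate-adjusted association of candidate SNPs.

Each candidate top SNP from the selection scan is tested for additive
association with the quantitative phenotype by ordinary least squares:
phenotype ~ intercept + dosage + age + height + weight + dive_duration
(+ age^2 on request) + leading genotype principal components. Testing only
the scan's candidates shrinks the multiple-testing burden to a Bonferroni
correction over a handful of SNPs. A median-based genomic-control factor and
an unpaired t-test utility for group comparisons round out the stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .containers import GenotypeMatrix
from .peaks import CandidateSet
from .popgen import pca

__all__ = [
    "AssociationRecord",
    "GroupComparison",
    "TwoStageReport",
    "ols_additive",
    "bonferroni_threshold",
    "gc_lambda_median",
    "ttest_groups",
    "run_two_stage",
]

DEFAULT_COVARIATES = ("age", "height", "weight", "dive_duration")


@dataclass
class AssociationRecord:
    variant_id: str
    beta: float
    se: float
    t_stat: float
    p_value: float
    n_used: int
    model_terms: list[str]


@dataclass
class GroupComparison:
    groups: tuple[str, str]
    means: tuple[float, float]
    sds: tuple[float, float]
    n: tuple[int, int]
    t_stat: float
    p_value: float
    equal_var: bool


@dataclass
class TwoStageReport:
    records: list[AssociationRecord]
    alpha: float
    threshold: float
    significant: list[str]
    n_candidates: int
    subset_population: str | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id": r.variant_id,
                    "beta": r.beta,
                    "se": r.se,
                    "t": r.t_stat,
                    "p": r.p_value,
                    "n": r.n_used,
                    "significant": r.variant_id in self.significant,
                }
                for r in self.records
            ]
        )

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "threshold": self.threshold,
            "n_candidates": self.n_candidates,
            "subset_population": self.subset_population,
            "significant": self.significant,
            "records": [
                {
                    "id": r.variant_id,
                    "beta": r.beta,
                    "se": r.se,
                    "t": r.t_stat,
                    "p": r.p_value,
                    "n": r.n_used,
                    "model_terms": r.model_terms,
                }
                for r in self.records
            ],
        }


def _check_full_rank(X: pd.DataFrame) -> None:
    """Raise naming the collinear column if the design is rank deficient."""
    mat = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank == X.shape[1]:
        return
    # walk the columns; the first column that does not increase the rank of
    # the preceding block is the redundant term
    for j in range(1, X.shape[1]):
        if np.linalg.matrix_rank(mat[:, : j + 1]) == np.linalg.matrix_rank(mat[:, :j]):
            raise ValueError(
                f"design matrix is rank deficient: column {X.columns[j]!r} is "
                "collinear with preceding terms"
            )
    raise ValueError("design matrix is rank deficient")


def ols_additive(
    genotype_dosage: Sequence[float] | np.ndarray,
    phenotypes: pd.DataFrame,
    pcs: np.ndarray | pd.DataFrame | None = None,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    include_age_squared: bool = False,
    variant_id: str = "snp",
    min_cases: int = 20,
) -> AssociationRecord:
    """OLS of the untransformed phenotype on allele dosage plus covariates.

    The genotype coefficient is reported in phenotype units per alternate
    allele with a two-sided t-based p-value on the residual degrees of
    freedom. Complete-case analysis: rows with any missing term are dropped.
    """
    dosage = np.asarray(genotype_dosage, dtype=float)
    if dosage.shape[0] != len(phenotypes):
        raise ValueError("dosage length must match the phenotype table")
    X = pd.DataFrame({"dosage": dosage}, index=phenotypes.index)
    for cov in covariates:
        if cov not in phenotypes.columns:
            raise KeyError(f"covariate {cov!r} missing from phenotype table")
        X[cov] = phenotypes[cov].to_numpy(dtype=float)
    if include_age_squared:
        if "age" not in X.columns:
            raise KeyError("age covariate required for the age^2 term")
        X["age_sq"] = X["age"] ** 2
    if pcs is not None:
        pcs = np.asarray(pcs, dtype=float)
        if pcs.shape[0] != len(phenotypes):
            raise ValueError("PC scores must match the phenotype table")
        for i in range(pcs.shape[1]):
            X[f"PC{i + 1}"] = pcs[:, i]

    y = phenotypes["phenotype"].to_numpy(dtype=float)
    complete = ~(np.isnan(y) | X.isna().any(axis=1).to_numpy())
    X, y = X[complete], y[complete]
    if len(X) < min_cases:
        raise ValueError(f"only {len(X)} complete cases (< {min_cases})")

    X = sm.add_constant(X, prepend=True, has_constant="add")
    if np.ptp(y) == 0:
        return AssociationRecord(
            variant_id=variant_id, beta=0.0, se=np.nan, t_stat=0.0, p_value=1.0,
            n_used=int(len(X)), model_terms=[c for c in X.columns if c != "const"],
        )
    _check_full_rank(X)
    fit = sm.OLS(y, X).fit()
    return AssociationRecord(
        variant_id=variant_id,
        beta=float(fit.params["dosage"]),
        se=float(fit.bse["dosage"]),
        t_stat=float(fit.tvalues["dosage"]),
        p_value=float(fit.pvalues["dosage"]),
        n_used=int(len(X)),
        model_terms=[c for c in X.columns if c != "const"],
    )


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha / m."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def gc_lambda_median(p_values: Sequence[float] | np.ndarray, min_p: int = 100) -> float:
    """Median-based genomic-control inflation factor.

    Transforms p-values to chi-square(1) quantiles and divides their median
    by the chi-square(1) median (~0.4549).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size < min_p:
        raise ValueError(f"need >= {min_p} p-values for a stable median")
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    chisq = stats.chi2.isf(p, df=1)
    return float(np.median(chisq) / stats.chi2.ppf(0.5, df=1))


def ttest_groups(
    values: Sequence[float] | np.ndarray,
    labels: Sequence[str] | np.ndarray,
    equal_var: bool = True,
) -> GroupComparison:
    """Two-sided unpaired t-test between two labelled groups.

    Pooled-variance by default; ``equal_var=False`` gives Welch's test.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = list(dict.fromkeys(labels))
    if len(groups) != 2:
        raise ValueError("exactly two group labels required")
    x = values[labels == groups[0]]
    y = values[labels == groups[1]]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 observations")
    t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    return GroupComparison(
        groups=(str(groups[0]), str(groups[1])),
        means=(float(x.mean()), float(y.mean())),
        sds=(float(x.std(ddof=1)), float(y.std(ddof=1))),
        n=(len(x), len(y)),
        t_stat=float(t),
        p_value=float(p),
        equal_var=equal_var,
    )


def run_two_stage(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    candidates: CandidateSet,
    alpha: float = 0.05,
    n_pcs: int = 10,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    include_age_squared: bool = False,
    subset_population: str | None = None,
) -> TwoStageReport:
    """Associate every candidate top SNP and apply Bonferroni control.

    PCs are computed on the genotype matrix of the analysed samples to
    control for population structure. ``subset_population`` restricts the
    analysis to one population (a within-population re-test).
    """
    if len(candidates) == 0:
        return TwoStageReport(
            records=[], alpha=alpha, threshold=bonferroni_threshold(alpha, 1),
            significant=[], n_candidates=0, subset_population=subset_population,
        )
    pheno = phenotypes.set_index("sample_id")
    shared = [s for s in genotypes.sample_ids if s in pheno.index]
    if subset_population is not None:
        pops = dict(zip(genotypes.sample_ids, genotypes.populations))
        shared = [s for s in shared if pops[s] == subset_population]
    if not shared:
        raise ValueError("no genotyped samples with phenotypes")
    sub = genotypes.select_samples(shared)
    pheno = pheno.loc[shared].reset_index()

    pcs = None
    if n_pcs > 0:
        k = min(n_pcs, sub.n_samples - 1, sub.n_variants)
        pcs = pca(sub, k=k).scores

    records = []
    for peak in candidates.peaks:
        dosage = sub.dosage(peak.top_snp)
        records.append(
            ols_additive(
                dosage,
                pheno,
                pcs=pcs,
                covariates=covariates,
                include_age_squared=include_age_squared,
                variant_id=peak.top_snp,
            )
        )
    threshold = bonferroni_threshold(alpha, len(candidates))
    significant = [r.variant_id for r in records if r.p_value <= threshold]
    return TwoStageReport(
        records=records,
        alpha=alpha,
        threshold=threshold,
        significant=significant,
        n_candidates=len(candidates),
        subset_population=subset_population,
    )
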