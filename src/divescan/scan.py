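"""Focal-population selection scan.

Per SNP, outgroup-rooted frequency contrasts ``y`` (each non-outgroup
population's frequency minus the outgroup's) are modelled as Gaussian with
mean zero and covariance ``s * C``, where ``s = p_bar (1 - p_bar)`` is the
per-SNP drift scale and ``C`` is the genome-wide contrast covariance. The
alternative multiplies the focal population's diagonal variance entry by a
scalar ``gamma >= 1`` estimated by maximum likelihood, yielding a
boundary-constrained one-parameter likelihood-ratio statistic (LLR, floored
at zero). Genomic control divides the statistics by an inflation factor
computed from 99th percentiles — not medians — because the null mass at zero
makes the median uninformative; calibrated p-values use the 50:50 mixture of
a point mass at zero and chi-square with one degree of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .containers import GenotypeMatrix
from .popgen import allele_frequencies

__all__ = [
    "DriftCovariance",
    "CalibrationResult",
    "estimate_drift_covariance",
    "scan_snp",
    "scan_genome",
    "calibrate_llrs",
]

GAMMA_MAX = 1e6
RIDGE = 1e-9


@dataclass
class DriftCovariance:
    """Genome-wide covariance of outgroup-rooted frequency contrasts.

    ``populations`` lists the contrast dimensions (focal first); ``C`` is the
    (K-1) x (K-1) positive-semidefinite covariance; ``n_snps_used`` counts the
    SNPs that entered the estimate.
    """

    populations: tuple[str, ...]
    outgroup: str
    C: np.ndarray
    n_snps_used: int
    focal_index: int = 0

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("C must be square")
        if C.shape[0] != len(self.populations):
            raise ValueError("C dimension must equal the number of contrasts")
        if not np.allclose(C, C.T, atol=1e-10):
            raise ValueError("C must be symmetric")
        if np.linalg.eigvalsh(C).min() < -1e-10:
            raise ValueError("C must be positive semidefinite")
        if not 0 <= self.focal_index < C.shape[0]:
            raise ValueError("focal index out of range")
        self.C = C

    @property
    def focal(self) -> str:
        return self.populations[self.focal_index]


@dataclass
class CalibrationResult:
    """Zero-inflation-aware genomic-control summary."""

    lambda_: float
    p99_observed: float
    p99_chisq1: float
    n_zero: int
    n_total: int
    basis: str = "retained"

    @property
    def fraction_zero(self) -> float:
        return self.n_zero / self.n_total


def contrasts(
    freqs: pd.DataFrame, focal: str, outgroup: str
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...], np.ndarray]:
    """Outgroup-rooted contrasts and drift scales from a frequency table.

    Returns ``(y, s, contrast_populations, usable)`` where ``y`` is
    (K-1, n_snps) with the focal contrast first, ``s = p_bar (1 - p_bar)``
    uses the unweighted across-population mean frequency, and ``usable``
    marks SNPs where every population is called and ``s > 0``.
    """
    pops = [c.removeprefix("freq_") for c in freqs.columns if c.startswith("freq_")]
    if focal not in pops or outgroup not in pops:
        raise KeyError("focal and outgroup must both appear in the frequency table")
    if len(pops) < 3:
        raise ValueError("need at least three populations for a rooted contrast model")
    order = [focal] + [p for p in pops if p not in (focal, outgroup)]
    F = np.array([freqs[f"freq_{p}"].to_numpy() for p in pops])
    p_out = freqs[f"freq_{outgroup}"].to_numpy()
    y = np.array([freqs[f"freq_{p}"].to_numpy() - p_out for p in order])
    p_bar = F.mean(axis=0)
    s = p_bar * (1 - p_bar)
    usable = ~np.isnan(F).any(axis=0) & (s > 0)
    return y, s, tuple(order), usable


def estimate_drift_covariance(
    freqs: pd.DataFrame,
    focal: str,
    outgroup: str,
    min_snps: int = 1000,
) -> DriftCovariance:
    """Estimate the genome-wide contrast covariance C = mean(y y' / s).

    SNPs with any uncalled population or zero drift scale are skipped; the
    result is projected onto the positive-semidefinite cone if sampling noise
    pushes an eigenvalue below zero.
    """
    y, s, order, usable = contrasts(freqs, focal, outgroup)
    n_used = int(usable.sum())
    if n_used == 0:
        raise ValueError("no usable SNPs: all monomorphic or uncalled")
    if n_used < min_snps:
        raise ValueError(
            f"only {n_used} usable SNPs (< {min_snps}); covariance would be unstable"
        )
    yu = y[:, usable]
    su = s[usable]
    C = np.einsum("in,jn->ij", yu / su, yu) / n_used
    C = (C + C.T) / 2
    evals, evecs = np.linalg.eigh(C)
    if evals.min() < 0:
        C = (evecs * np.maximum(evals, 0.0)) @ evecs.T
    return DriftCovariance(populations=order, outgroup=outgroup, C=C, n_snps_used=n_used)


# ------------------------------------------------------------------ per SNP

def _gaussian_m2ll(y: np.ndarray, cov: np.ndarray) -> float:
    """-2 log density of N(0, cov) at y, up to the additive constant."""
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        return math.inf
    return float(logdet + y @ np.linalg.solve(cov, y))


def scan_snp(
    y: np.ndarray,
    s: float,
    model: DriftCovariance,
    tol: float = 1e-8,
) -> tuple[float, float]:
    """Likelihood-ratio statistic for one SNP.

    Returns ``(llr, gamma_hat)``. The focal variance scalar gamma is found by
    bounded numerical maximisation of the Gaussian log-likelihood over
    ``log gamma`` in ``[0, log 1e6]``; the statistic is floored at zero, so
    ``llr = 0`` exactly when the boundary ``gamma = 1`` is optimal.
    """
    if s <= 0:
        raise ValueError("drift scale s must be positive")
    y = np.asarray(y, dtype=float)
    f = model.focal_index
    C = model.C
    # ridge only when near-singular, so well-posed models are untouched
    if not np.isfinite(np.linalg.cond(C)) or np.linalg.cond(C) > 1e10:
        C = C + RIDGE * max(np.trace(C) / C.shape[0], 1.0) * np.eye(C.shape[0])

    # At the gamma = 1 boundary the likelihood is decreasing in gamma unless
    # the focal deviation exceeds its null scale; detect that analytically to
    # avoid a needless optimiser run on the majority of SNPs.
    A = np.linalg.inv(C)
    w = float((A @ y)[f])
    z = w * w / (s * A[f, f])
    if z <= 1.0:
        return 0.0, 1.0

    def cov_at(log_gamma: float) -> np.ndarray:
        Cg = C.copy()
        Cg[f, f] = Cg[f, f] * math.exp(log_gamma)
        return s * Cg

    null_m2ll = _gaussian_m2ll(y, cov_at(0.0))

    res = minimize_scalar(
        lambda lg: _gaussian_m2ll(y, cov_at(lg)),
        bounds=(0.0, math.log(GAMMA_MAX)),
        method="bounded",
        options={"xatol": tol},
    )
    gamma_hat = math.exp(res.x)
    llr = null_m2ll - float(res.fun)
    if llr <= 0:
        return 0.0, 1.0
    return llr, gamma_hat


def scan_genome(
    genotypes: GenotypeMatrix,
    focal: str,
    outgroup: str,
    model: DriftCovariance | None = None,
    min_snps: int = 1000,
) -> pd.DataFrame:
    """Run the scan over every usable SNP.

    Estimates the drift covariance from the genome-wide data (unless a
    pre-estimated ``model`` is supplied), then applies the per-SNP test.
    Returns a coordinate-sorted table with columns ``id, chrom, pos, s,
    gamma_hat, llr``; SNPs that cannot be tested (monomorphic across
    populations or with an uncalled population) are omitted.
    """
    freqs = allele_frequencies(genotypes)
    if model is None:
        model = estimate_drift_covariance(freqs, focal, outgroup, min_snps=min_snps)
    y, s, order, usable = contrasts(freqs, focal, outgroup)
    if tuple(order) != tuple(model.populations):
        raise ValueError("frequency table populations do not match the covariance model")
    idx = np.flatnonzero(usable)
    llrs = np.empty(idx.size)
    gammas = np.empty(idx.size)
    for k, j in enumerate(idx):
        llrs[k], gammas[k] = scan_snp(y[:, j], float(s[j]), model)
    out = pd.DataFrame(
        {
            "id": freqs["id"].to_numpy()[idx],
            "chrom": freqs["chrom"].to_numpy()[idx],
            "pos": freqs["pos"].to_numpy()[idx],
            "s": s[idx],
            "gamma_hat": gammas,
            "llr": llrs,
        }
    )
    return out.reset_index(drop=True)


# -------------------------------------------------------------- calibration

def calibrate_llrs(
    scan: pd.DataFrame | np.ndarray,
    quantile: float = 0.99,
    basis: str = "retained",
) -> tuple[CalibrationResult, pd.DataFrame | None]:
    """Zero-inflation-aware genomic control.

    Discards the lowest half of the statistics (ties at zero broken
    arbitrarily: every discarded value is <= every retained one), computes
    the inflation factor ``lambda = P99(observed) / P99(chi2_1)`` on the
    retained half (or on all statistics with ``basis='all'``), divides every
    statistic by lambda, and assigns mixture p-values: ``p = 1`` where
    ``llr = 0``, else ``0.5 * chi2_1 survival(llr / lambda)``.
    """
    if isinstance(scan, pd.DataFrame):
        llr = scan["llr"].to_numpy(dtype=float)
    else:
        llr = np.asarray(scan, dtype=float)
        scan = None
    if llr.size == 0:
        raise ValueError("empty scan")
    if np.all(llr == 0):
        raise ValueError("degenerate scan: all likelihood ratios are zero")
    if basis not in ("retained", "all"):
        raise ValueError("basis must be 'retained' or 'all'")

    srt = np.sort(llr)
    retained = srt[llr.size // 2 :]
    ref = retained if basis == "retained" else srt
    p99_obs = float(np.quantile(ref, quantile))
    p99_chi = float(stats.chi2.ppf(quantile, df=1))
    if p99_obs <= 0:
        raise ValueError("degenerate scan: the observed calibration quantile is zero")
    lam = p99_obs / p99_chi
    result = CalibrationResult(
        lambda_=lam,
        p99_observed=p99_obs,
        p99_chisq1=p99_chi,
        n_zero=int(np.sum(llr == 0)),
        n_total=int(llr.size),
        basis=basis,
    )
    if scan is not None:
        scan = scan.copy()
        scan["llr_corrected"] = scan["llr"] / lam
        scan["p_calibrated"] = np.where(
            scan["llr"] == 0, 1.0, 0.5 * stats.chi2.sf(scan["llr_corrected"], df=1)
        )
        return result, scan
    return result, None
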