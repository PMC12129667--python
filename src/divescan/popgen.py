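"""Population-structure and diversity statistics.

Per-population allele frequencies, the Weir & Cockerham (1984) F_ST
estimator, windowed nucleotide diversity with the neutral-theory effective
population size Ne = pi / (4 mu), generation-time conversion, and genotype
PCA on standardised dosages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix

__all__ = [
    "FstResult",
    "PcaResult",
    "allele_frequencies",
    "wc_fst",
    "windowed_pi",
    "ne_from_pi",
    "generations_to_years",
    "pca",
]


def allele_frequencies(
    genotypes: GenotypeMatrix, populations: list[str] | None = None
) -> pd.DataFrame:
    """Per-variant, per-population alternate-allele frequencies.

    Returns a DataFrame with, for each population ``P``, columns ``freq_P``
    (NaN when no genotype is called), ``count_P`` (alternate-allele count)
    and ``nhap_P`` (called haplotypes).
    """
    if populations is None:
        populations = genotypes.population_names()
    labels = genotypes.populations
    out = pd.DataFrame(
        {
            "id": genotypes.variants["id"],
            "chrom": genotypes.variants["chrom"],
            "pos": genotypes.variants["pos"],
        }
    )
    for pop in populations:
        mask = labels == pop
        if not mask.any():
            raise KeyError(f"population {pop!r} has no samples")
        calls = genotypes.calls[mask]
        valid = calls != MISSING
        nhap = 2 * valid.sum(axis=0)
        count = np.where(valid, calls, 0).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            freq = np.where(nhap > 0, count / np.maximum(nhap, 1), np.nan)
        out[f"freq_{pop}"] = freq
        out[f"count_{pop}"] = count
        out[f"nhap_{pop}"] = nhap
    return out


# ------------------------------------------------------------------- F_ST

@dataclass
class FstResult:
    """Weir-Cockerham variance components and the ratio-of-averages F_ST."""

    a: np.ndarray          # between-population component, per variant
    b: np.ndarray          # between-individual within-population
    c: np.ndarray          # within-individual (heterozygosity / 2)
    populations: tuple[str, str]

    @property
    def fst(self) -> float:
        denom = np.nansum(self.a + self.b + self.c)
        if denom == 0:
            raise ValueError("F_ST undefined: no variation in either population")
        return float(np.nansum(self.a) / denom)

    @property
    def per_variant_fst(self) -> np.ndarray:
        denom = self.a + self.b + self.c
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(denom != 0, self.a / denom, np.nan)


def wc_fst(genotypes: GenotypeMatrix, populations: tuple[str, str]) -> FstResult:
    """Two-population Weir & Cockerham (1984) F_ST.

    The multi-SNP estimate is the ratio of averages, sum(a) / sum(a+b+c) —
    not the average of per-SNP ratios.
    """
    if len(populations) != 2:
        raise ValueError("exactly two populations required")
    labels = genotypes.populations
    r = 2
    n_i, p_i, h_i = [], [], []
    for pop in populations:
        mask = labels == pop
        if mask.sum() < 2:
            raise ValueError(f"population {pop!r} needs >= 2 samples")
        calls = genotypes.calls[mask]
        valid = calls != MISSING
        n = valid.sum(axis=0).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(n > 0, np.where(valid, calls, 0).sum(axis=0) / (2 * np.maximum(n, 1)), np.nan)
            h = np.where(n > 0, ((calls == 1) & valid).sum(axis=0) / np.maximum(n, 1), np.nan)
        n_i.append(n)
        p_i.append(p)
        h_i.append(h)
    n_i = np.array(n_i)
    p_i = np.array(p_i)
    h_i = np.array(h_i)

    usable = (n_i > 0).all(axis=0) & (n_i.sum(axis=0) > 2)
    n_bar = n_i.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        n_c = (r * n_bar - (n_i**2).sum(axis=0) / (r * n_bar)) / (r - 1)
        p_bar = (n_i * p_i).sum(axis=0) / (r * n_bar)
        s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum(axis=0) / (r * n_bar)

        a = (n_bar / n_c) * (
            s2
            - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar)
            - (r - 1) / r * s2
            - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2

    a = np.where(usable, a, np.nan)
    b = np.where(usable, b, np.nan)
    c = np.where(usable, c, np.nan)
    return FstResult(a=a, b=b, c=c, populations=(populations[0], populations[1]))


# ------------------------------------------------------------ diversity

def windowed_pi(
    genotypes: GenotypeMatrix,
    window_bp: int = 250_000_000,
    population: str | None = None,
    mu: float = 1.25e-8,
) -> pd.DataFrame:
    """Windowed nucleotide diversity and the derived Ne estimate.

    Per window, pi is the sum over SNPs of the unbiased per-site expected
    heterozygosity ``2 p (1-p) * 2n/(2n-1)`` divided by the window length in
    bp (comparable to vcftools --window-pi); ``ne`` applies pi/(4 mu).
    Windows are 1-based inclusive ``[start, end]``.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    if population is None:
        mask = np.ones(genotypes.n_samples, dtype=bool)
    else:
        mask = genotypes.populations == population
        if not mask.any():
            raise KeyError(f"population {population!r} has no samples")
    calls = genotypes.calls[mask]
    valid = calls != MISSING
    nhap = 2 * valid.sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(nhap > 0, np.where(valid, calls, 0).sum(axis=0) / np.maximum(nhap, 1), np.nan)
        site_pi = np.where(
            nhap > 1, 2 * p * (1 - p) * nhap / np.maximum(nhap - 1, 1), np.nan
        )

    rows = []
    var = genotypes.variants
    for chrom, grp in var.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        pi_here = site_pi[grp.index.to_numpy()]
        w = (pos - 1) // window_bp
        for wi in np.unique(w):
            sel = w == wi
            start = int(wi * window_bp + 1)
            end = int((wi + 1) * window_bp)
            pi_val = float(np.nansum(pi_here[sel]) / window_bp)
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "n_snps": int(sel.sum()),
                    "pi": pi_val,
                    "ne": ne_from_pi(pi_val, mu),
                    "mu": mu,
                }
            )
    return pd.DataFrame(rows)


def ne_from_pi(pi: float, mu: float = 1.25e-8) -> float:
    """Neutral-theory effective population size, Ne = pi / (4 mu)."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    if pi < 0:
        raise ValueError("pi must be >= 0")
    return pi / (4.0 * mu)


def generations_to_years(generations: float, generation_time: float = 27.0) -> float:
    """Convert a generation count to years (default 27 years/generation)."""
    if generations <= 0 or generation_time <= 0:
        raise ValueError("generations and generation_time must be positive")
    return generations * generation_time


# ------------------------------------------------------------------- PCA

@dataclass
class PcaResult:
    scores: np.ndarray        # (n_samples, k)
    eigenvalues: np.ndarray   # length k, nonincreasing
    sample_ids: list[str]
    n_variants_used: int

    def as_frame(self) -> pd.DataFrame:
        cols = {f"PC{i + 1}": self.scores[:, i] for i in range(self.scores.shape[1])}
        return pd.DataFrame({"sample_id": self.sample_ids, **cols})


def pca(genotypes: GenotypeMatrix, k: int = 10) -> PcaResult:
    """Genotype PCA on standardised dosages.

    Missing calls are mean-imputed, dosages centred by ``2 p`` and scaled by
    ``sqrt(2 p (1 - p))``; monomorphic variants are dropped. Scores are the
    eigenvectors of the sample-by-sample covariance scaled by the square root
    of their eigenvalues.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > min(genotypes.n_samples - 1, genotypes.n_variants):
        raise ValueError("k exceeds min(samples - 1, variants)")
    freq = genotypes.alt_allele_frequency()
    poly = ~np.isnan(freq) & (freq > 0) & (freq < 1)
    if not poly.any():
        raise ValueError("all variants monomorphic; PCA undefined")
    calls = genotypes.calls[:, poly].astype(float)
    p = freq[poly]
    mean = 2 * p
    calls = np.where(calls == MISSING, mean, calls)
    std = np.sqrt(2 * p * (1 - p))
    X = (calls - mean) / std
    n_var = int(poly.sum())
    cov = X @ X.T / n_var
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:k]
    evals = np.maximum(evals[order], 0.0)
    scores = evecs[:, order] * np.sqrt(evals)
    return PcaResult(
        scores=scores,
        eigenvalues=evals,
        sample_ids=genotypes.sample_ids,
        n_variants_used=n_var,
    )
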