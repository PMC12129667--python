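"""Variant- and sample-level quality control.

Implements the filters applied upstream of the selection scan: minor-allele
frequency, one-sided heterozygote-excess exact test, apparent fixed-difference
(allele-flip) detection between merged panels, and relatedness pruning based
on a method-of-moments K0 estimate (the proportion of the genome where a pair
shares zero alleles identical by descent; ~1 for unrelated pairs, ~0 for
duplicates and parent-offspring pairs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix

__all__ = [
    "FilterReport",
    "RelatednessEstimate",
    "FlipReport",
    "minor_allele_frequency",
    "maf_filter",
    "exchet_test",
    "exchet_pvalues",
    "apply_exchet_filter",
    "variant_qc_table",
    "estimate_k0",
    "pairwise_k0",
    "prune_related",
    "detect_allele_flips",
]


@dataclass
class FilterReport:
    filter_name: str
    n_input: int
    n_removed: int

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed


@dataclass
class RelatednessEstimate:
    pair: tuple[str, str]
    k0: float
    n_snps: int


@dataclass
class FlipReport:
    flagged_variants: list[str]
    rule: str


# --------------------------------------------------------------------- MAF

def minor_allele_frequency(genotypes: GenotypeMatrix) -> np.ndarray:
    """Per-variant minor-allele frequency over all non-missing calls."""
    freq = genotypes.alt_allele_frequency()
    return np.where(np.isnan(freq), np.nan, np.minimum(freq, 1.0 - freq))


def maf_filter(
    genotypes: GenotypeMatrix, threshold: float = 0.01
) -> tuple[GenotypeMatrix, FilterReport]:
    """Retain variants with MAF >= ``threshold`` (computed across all samples)."""
    if not 0 <= threshold < 0.5:
        raise ValueError("threshold must lie in [0, 0.5)")
    if genotypes.n_variants == 0:
        raise ValueError("empty genotype matrix")
    maf = minor_allele_frequency(genotypes)
    keep = np.flatnonzero(~np.isnan(maf) & (maf >= threshold))
    report = FilterReport("maf", genotypes.n_variants, genotypes.n_variants - keep.size)
    return genotypes.take_variants(keep), report


# ----------------------------------------------------------------- ExcHet

def _het_log_weights(n_rare: int, n_total: int) -> tuple[np.ndarray, np.ndarray]:
    """Unnormalised log-probabilities of every feasible heterozygote count
    under the exact conditional (Levene/Haldane) distribution given allele
    counts. ``n_rare`` is the rarer allele count, ``n_total`` the diploid
    sample size. Returns (het counts, log weights)."""
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    # P(h) proportional to  n! / (h! ((n_rare-h)/2)! ((2n - n_rare - h)/2)!) * 2^h
    from scipy.special import gammaln

    n_common = 2 * n_total - n_rare
    logs = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln((n_rare - hets) / 2 + 1)
        - gammaln((n_common - hets) / 2 + 1)
    )
    return hets, logs


def exchet_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """One-sided Hardy-Weinberg exact test against heterozygote excess.

    Returns P(het count >= observed | allele counts) under the exact
    conditional distribution of heterozygote count given the allele counts.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotype required")
    if n_Aa == 0:
        return 1.0
    n_alt = n_Aa + 2 * n_aa
    n_rare = min(n_alt, 2 * n - n_alt)
    hets, logs = _het_log_weights(n_rare, n)
    w = np.exp(logs - logs.max())
    w /= w.sum()
    return float(min(1.0, w[hets >= n_Aa].sum()))


def exchet_pvalues(genotypes: GenotypeMatrix) -> np.ndarray:
    """Per-variant one-sided heterozygote-excess exact p-values."""
    calls = genotypes.calls
    valid = calls != MISSING
    n_het = ((calls == 1) & valid).sum(axis=0)
    n_hom_alt = ((calls == 2) & valid).sum(axis=0)
    n_hom_ref = ((calls == 0) & valid).sum(axis=0)
    out = np.ones(genotypes.n_variants)
    for j in np.flatnonzero(n_het > 0):
        out[j] = exchet_test(int(n_hom_ref[j]), int(n_het[j]), int(n_hom_alt[j]))
    return out


def apply_exchet_filter(
    genotypes: GenotypeMatrix, alpha: float = 1e-6
) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove variants whose heterozygote-excess p-value is <= ``alpha``."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie strictly inside (0, 1)")
    p = exchet_pvalues(genotypes)
    keep = np.flatnonzero(p > alpha)
    report = FilterReport("exchet", genotypes.n_variants, genotypes.n_variants - keep.size)
    return genotypes.take_variants(keep), report


def variant_qc_table(genotypes: GenotypeMatrix, maf_threshold: float = 0.01,
                     exchet_alpha: float = 1e-6) -> pd.DataFrame:
    """Per-variant QC summary: MAF, ExcHet p and pass flags."""
    maf = minor_allele_frequency(genotypes)
    p = exchet_pvalues(genotypes)
    return pd.DataFrame(
        {
            "id": genotypes.variants["id"],
            "maf": maf,
            "exchet_p": p,
            "pass_maf": ~np.isnan(maf) & (maf >= maf_threshold),
            "pass_exchet": p > exchet_alpha,
        }
    )


# ------------------------------------------------------------- relatedness

def _ibs0_expectation(freq: np.ndarray) -> np.ndarray:
    """P(IBS0) per site for two unrelated HWE individuals: 2 p^2 (1-p)^2."""
    return 2.0 * freq**2 * (1.0 - freq) ** 2


def estimate_k0(
    genotypes: GenotypeMatrix,
    pair: tuple[str, str],
    min_snps: int = 100,
) -> RelatednessEstimate:
    """Method-of-moments estimate of K0 = P(IBD = 0) for one sample pair.

    Counts opposite-homozygote (IBS0) sites, which can only occur on the
    IBD-0 fraction of the genome, and divides by the count expected for a
    fully unrelated pair given the sample allele frequencies.
    """
    i = genotypes.sample_index(pair[0])
    j = genotypes.sample_index(pair[1])
    gi, gj = genotypes.calls[i], genotypes.calls[j]
    shared = (gi != MISSING) & (gj != MISSING)
    if shared.sum() < min_snps:
        raise ValueError(
            f"only {int(shared.sum())} overlapping non-missing SNPs "
            f"(< {min_snps}); K0 estimate would be unreliable"
        )
    freq = genotypes.alt_allele_frequency()
    expected = np.nansum(np.where(shared, _ibs0_expectation(freq), 0.0))
    ibs0 = int(np.sum(shared & (((gi == 0) & (gj == 2)) | ((gi == 2) & (gj == 0)))))
    if expected <= 0:
        raise ValueError("no informative sites for the K0 denominator")
    k0 = min(1.0, max(0.0, ibs0 / expected))
    return RelatednessEstimate(pair=(pair[0], pair[1]), k0=k0, n_snps=int(shared.sum()))


def pairwise_k0(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """K0 for every sample pair (vectorised over pairs)."""
    calls = genotypes.calls
    valid = (calls != MISSING).astype(np.float64)
    hom_ref = ((calls == 0)).astype(np.float64)
    hom_alt = ((calls == 2)).astype(np.float64)
    freq = np.nan_to_num(genotypes.alt_allele_frequency(), nan=0.0)
    e0 = _ibs0_expectation(freq)
    ibs0 = hom_ref @ hom_alt.T + hom_alt @ hom_ref.T
    expected = (valid * e0) @ valid.T
    n_shared = valid @ valid.T
    ids = genotypes.sample_ids
    rows = []
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            exp_ij = expected[i, j]
            k0 = np.clip(ibs0[i, j] / exp_ij, 0.0, 1.0) if exp_ij > 0 else np.nan
            rows.append((ids[i], ids[j], k0, int(n_shared[i, j])))
    return pd.DataFrame(rows, columns=["sample_1", "sample_2", "k0", "n_snps"])


def prune_related(
    genotypes: GenotypeMatrix,
    threshold: float = 0.75,
    comparator: str = "less",
) -> tuple[list[str], list[str]]:
    """Iteratively exclude one member of each related pair.

    A pair is flagged as related when its K0 falls on the ``comparator`` side
    of ``threshold`` (default ``"less"``: low K0 means the pair shares IBD
    segments). Each round excludes the later-in-input-order member of every
    flagged pair, then relatedness is recomputed; iteration stops when no
    flagged pair remains.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if comparator not in ("less", "greater"):
        raise ValueError("comparator must be 'less' or 'greater'")
    flag: Callable[[np.ndarray], np.ndarray]
    flag = (lambda k0: k0 < threshold) if comparator == "less" else (lambda k0: k0 > threshold)

    order = {s: i for i, s in enumerate(genotypes.sample_ids)}
    retained = list(genotypes.sample_ids)
    excluded: list[str] = []
    while True:
        sub = genotypes.select_samples(retained)
        table = pairwise_k0(sub)
        flagged = table[flag(table["k0"].to_numpy())]
        if flagged.empty:
            break
        drop = set()
        for _, row in flagged.iterrows():
            later = max((row["sample_1"], row["sample_2"]), key=lambda s: order[s])
            drop.add(later)
        excluded.extend(sorted(drop, key=lambda s: order[s]))
        retained = [s for s in retained if s not in drop]
        if len(retained) < 2:
            break
    return retained, excluded


# -------------------------------------------------------------- allele flips

def detect_allele_flips(
    freqs_panel_a: pd.Series | np.ndarray,
    freqs_panel_b: pd.Series | np.ndarray,
    variant_ids: Sequence[str] | None = None,
    eps: float = 0.0,
) -> FlipReport:
    """Flag apparent fixed differences between two merged panels.

    A variant is flagged when one panel is fixed (within ``eps``) for the
    reference allele and the other fixed for the alternate — the signature of
    an allele-coding flip rather than real differentiation.
    """
    fa = np.asarray(freqs_panel_a, dtype=float)
    fb = np.asarray(freqs_panel_b, dtype=float)
    if fa.shape != fb.shape:
        raise ValueError("panels must share the variant set")
    if variant_ids is None:
        if isinstance(freqs_panel_a, pd.Series):
            variant_ids = list(freqs_panel_a.index)
        else:
            variant_ids = [str(i) for i in range(fa.size)]
    both = ~np.isnan(fa) & ~np.isnan(fb)
    flip = both & (
        ((fa <= eps) & (fb >= 1 - eps)) | ((fa >= 1 - eps) & (fb <= eps))
    )
    flagged = [v for v, f in zip(variant_ids, flip) if f]
    return FlipReport(
        flagged_variants=flagged,
        rule=f"fixed-difference (eps={eps:g})",
    )
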