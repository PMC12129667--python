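"""Core in-memory containers shared by every analysis stage.

The central object is :class:`GenotypeMatrix`: a samples x variants matrix of
alternate-allele dosages (0/1/2, ``-1`` for missing) with per-sample population
labels and per-variant coordinates. All QC filters, population-genetic
statistics and the selection scan operate on this container; VCF input/output
lives in :mod:`divescan.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Biallelic diploid genotypes for labelled samples.

    Parameters
    ----------
    calls
        ``(n_samples, n_variants)`` integer array of alternate-allele dosages
        in ``{0, 1, 2}`` with ``-1`` marking missing calls.
    samples
        DataFrame with columns ``sample_id`` and ``population``; row order is
        the row order of ``calls``.
    variants
        DataFrame with columns ``chrom, pos, id, ref, alt``; positions are
        1-based and strictly increasing within a chromosome.
    """

    calls: np.ndarray
    samples: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D samples x variants array")
        if not np.issubdtype(self.calls.dtype, np.integer):
            raise ValueError("calls must be an integer dosage array")
        bad = (self.calls > 2) | (self.calls < MISSING)
        if bad.any():
            raise ValueError("dosages must be in {0,1,2} or -1 (missing)")
        self.samples = self.samples.reset_index(drop=True)
        self.variants = self.variants.reset_index(drop=True)
        for col in ("sample_id", "population"):
            if col not in self.samples.columns:
                raise ValueError(f"samples table lacks required column {col!r}")
        for col in VARIANT_COLUMNS:
            if col not in self.variants.columns:
                raise ValueError(f"variants table lacks required column {col!r}")
        if len(self.samples) != self.calls.shape[0]:
            raise ValueError("samples table and calls row count disagree")
        if len(self.variants) != self.calls.shape[1]:
            raise ValueError("variants table and calls column count disagree")
        for _, grp in self.variants.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("positions must be strictly increasing within a chromosome")

    # ------------------------------------------------------------------ shape
    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_variants(self) -> int:
        return self.calls.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return self.samples["sample_id"].tolist()

    @property
    def populations(self) -> np.ndarray:
        return self.samples["population"].to_numpy()

    def population_names(self) -> list[str]:
        """Population labels in first-appearance order."""
        return list(dict.fromkeys(self.samples["population"]))

    # ---------------------------------------------------------------- subsets
    def take_variants(self, index: Iterable[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(list(index) if not isinstance(index, np.ndarray) else index)
        return GenotypeMatrix(
            calls=self.calls[:, index].copy(),
            samples=self.samples.copy(),
            variants=self.variants.iloc[index].reset_index(drop=True),
        )

    def take_samples(self, index: Iterable[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(list(index) if not isinstance(index, np.ndarray) else index)
        return GenotypeMatrix(
            calls=self.calls[index].copy(),
            samples=self.samples.iloc[index].reset_index(drop=True),
            variants=self.variants.copy(),
        )

    def select_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        order = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in order]
        if missing:
            raise KeyError(f"samples not present: {missing[:5]}")
        return self.take_samples([order[s] for s in sample_ids])

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not present") from None

    def variant_index(self, variant_id: str) -> int:
        hits = np.flatnonzero(self.variants["id"].to_numpy() == variant_id)
        if hits.size == 0:
            raise KeyError(f"variant {variant_id!r} not present")
        return int(hits[0])

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.calls.copy(), self.samples.copy(), self.variants.copy())

    # ------------------------------------------------------------ frequencies
    def alt_allele_frequency(self, sample_mask: np.ndarray | None = None) -> np.ndarray:
        """Per-variant alternate-allele frequency over non-missing calls.

        Returns NaN where no sample is called.
        """
        calls = self.calls if sample_mask is None else self.calls[sample_mask]
        valid = calls != MISSING
        n_hap = 2.0 * valid.sum(axis=0)
        alt = np.where(valid, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(n_hap > 0, alt / np.maximum(n_hap, 1), np.nan)
        return freq

    def dosage(self, variant_id: str) -> np.ndarray:
        """Alternate-allele dosage vector for one variant (float, NaN missing)."""
        j = self.variant_index(variant_id)
        d = self.calls[:, j].astype(float)
        d[d == MISSING] = np.nan
        return d


def synthetic_variant_table(
    n_snps: int,
    spacing_bp: int = 3000,
    snps_per_chrom: int = 100_000,
    id_prefix: str = "snp",
) -> pd.DataFrame:
    """Synthetic coordinates: one chromosome per ``snps_per_chrom`` SNPs,
    1-based positions at fixed ``spacing_bp``."""
    idx = np.arange(n_snps)
    chrom_no = idx // snps_per_chrom + 1
    within = idx % snps_per_chrom
    return pd.DataFrame(
        {
            "chrom": [f"chr{c}" for c in chrom_no],
            "pos": within * spacing_bp + 1,
            "id": [f"{id_prefix}{i}" for i in idx],
            "ref": "A",
            "alt": "G",
        }
    )
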