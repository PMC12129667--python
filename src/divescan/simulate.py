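"""Drift-structured synthetic data: allele frequencies, genotypes, phenotypes
and injected artifacts.

The generator emulates three populations splitting from a shared ancestor
under pure drift: a focal island-like population (default ``JEJ``), a sister
mainland-like population (``KOR``) and a deeper outgroup (``CHS``). Each
branch applies a Balding-Nichols step: the daughter frequency is Beta
distributed with mean equal to the ancestral frequency and variance
``F * p0 * (1 - p0)``, which keeps frequencies inside (0, 1) without clipping.

Selected loci receive an inflated focal drift variance
(``F_focal * selection_boost``). A stronger, sweep-like signal can be injected
with :class:`SweepSpec`: the focal frequency at a chosen SNP is displaced to a
target value and flanking SNPs receive a decaying fraction of the same
displacement, emulating the positional footprint of hitchhiking without
modelling haplotype LD.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, synthetic_variant_table

__all__ = [
    "SimulationParams",
    "SweepSpec",
    "SimulatedPanel",
    "PhenotypeParams",
    "ArtifactTruth",
    "simulate_panel",
    "sample_genotypes",
    "simulate_phenotype",
    "inject_artifacts",
]


@dataclass(frozen=True)
class SweepSpec:
    """Directional focal-frequency displacement with a decaying flank profile.

    ``center_index`` names the swept SNP; its ancestral frequency is pinned to
    ``root_freq`` and its focal-population frequency to ``focal_freq``. The
    ``i``-th flanking SNP on either side is pinned to the same root and
    displaced by ``flank_weights[i]`` of the full shift.
    """

    center_index: int
    root_freq: float = 0.07
    focal_freq: float = 0.33
    flank_weights: tuple[float, ...] = (0.55, 0.40, 0.30)

    def __post_init__(self) -> None:
        if not 0 < self.root_freq < 1 or not 0 < self.focal_freq < 1:
            raise ValueError("sweep frequencies must lie in (0, 1)")
        if any(not 0 <= w <= 1 for w in self.flank_weights):
            raise ValueError("flank weights must lie in [0, 1]")


@dataclass(frozen=True)
class SimulationParams:
    """Conditions of a drift simulation.

    Defaults mirror the study system: three populations with a focal-sister
    differentiation around F_ST 0.004 and a deeper outgroup, diploid sample
    sizes (57, 84, 50), and a per-site mutation rate of 1.25e-8 used only for
    diversity-based summaries.
    """

    n_snps: int = 20_000
    population_names: tuple[str, ...] = ("JEJ", "KOR", "CHS")
    branch_drift: tuple[float, ...] = (0.004, 0.004, 0.02)
    root_freq_law: tuple = ("uniform", 0.05, 0.95)
    sample_sizes: tuple[int, ...] = (57, 84, 50)
    n_selected: int = 0
    selection_boost: float = 50.0
    selected_loci: tuple[int, ...] | None = None
    sweeps: tuple[SweepSpec, ...] = ()
    mu: float = 1.25e-8
    spacing_bp: int = 3000
    snps_per_chrom: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps <= 0:
            raise ValueError("n_snps must be positive")
        k = len(self.population_names)
        if k < 2:
            raise ValueError("need at least two populations")
        if len(self.branch_drift) != k or len(self.sample_sizes) != k:
            raise ValueError("branch_drift and sample_sizes must match population count")
        if any(f < 0 for f in self.branch_drift):
            raise ValueError("drift variances must be >= 0")
        if any(n < 2 for n in self.sample_sizes):
            raise ValueError("sample sizes must be >= 2")
        if self.selection_boost < 1:
            raise ValueError("selection_boost must be >= 1")
        if self.n_selected < 0 or self.n_selected > self.n_snps:
            raise ValueError("n_selected out of range")
        law = self.root_freq_law
        if law[0] == "uniform":
            lo, hi = law[1], law[2]
            if not (0 < lo < hi < 1):
                raise ValueError("uniform root law bounds must satisfy 0 < lo < hi < 1")
        elif law[0] == "beta":
            if law[1] <= 0 or law[2] <= 0:
                raise ValueError("beta root law parameters must be positive")
        else:
            raise ValueError(f"unknown root frequency law {law[0]!r}")
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.n_selected or self.selected_loci:
            if self.branch_drift[0] * self.selection_boost >= 1:
                raise ValueError(
                    "degenerate Beta parameters: focal drift x selection_boost "
                    "must stay below 1"
                )

    @property
    def focal(self) -> str:
        return self.population_names[0]

    @property
    def outgroup(self) -> str:
        return self.population_names[-1]


@dataclass
class SimulatedPanel:
    """True per-population allele frequencies plus provenance."""

    root_freqs: np.ndarray                 # (n_snps,)
    pop_freqs: np.ndarray                  # (n_pops, n_snps)
    selected_loci: np.ndarray              # indices with boosted focal drift
    sweep_members: np.ndarray              # indices displaced by sweeps
    params: SimulationParams

    @property
    def population_names(self) -> tuple[str, ...]:
        return self.params.population_names


def _draw_root(params: SimulationParams, rng: np.random.Generator) -> np.ndarray:
    law = params.root_freq_law
    if law[0] == "uniform":
        return rng.uniform(law[1], law[2], params.n_snps)
    return rng.beta(law[1], law[2], params.n_snps)


def _balding_nichols(p0: np.ndarray, F: np.ndarray | float, rng: np.random.Generator) -> np.ndarray:
    """One drift step: Beta(p0(1-F)/F, (1-p0)(1-F)/F); F=0 is the identity."""
    F = np.broadcast_to(np.asarray(F, dtype=float), p0.shape)
    out = p0.copy()
    # frequencies at 0/1 are absorbing states; only interior loci drift
    drifting = (F > 0) & (p0 > 0) & (p0 < 1)
    if drifting.any():
        Fd = F[drifting]
        p = p0[drifting]
        a = p * (1 - Fd) / Fd
        b = (1 - p) * (1 - Fd) / Fd
        out[drifting] = rng.beta(a, b)
    return out


def simulate_panel(params: SimulationParams) -> SimulatedPanel:
    """Draw ancestral and per-population allele frequencies.

    Selected loci use ``F_focal * selection_boost`` on the focal branch; sweep
    SNPs additionally pin the focal frequency to a deterministic displacement
    profile (see :class:`SweepSpec`).
    """
    rng = np.random.default_rng(params.seed)
    p0 = _draw_root(params, rng)

    if params.selected_loci is not None:
        selected = np.asarray(sorted(params.selected_loci), dtype=int)
        if selected.size and (selected.min() < 0 or selected.max() >= params.n_snps):
            raise ValueError("selected_loci out of range")
        if selected.size != params.n_selected and params.n_selected:
            selected = selected  # explicit list wins over the count
    elif params.n_selected:
        selected = np.sort(rng.choice(params.n_snps, size=params.n_selected, replace=False))
    else:
        selected = np.array([], dtype=int)

    sweep_members: list[int] = []
    for sw in params.sweeps:
        k = len(sw.flank_weights)
        lo, hi = sw.center_index - k, sw.center_index + k
        if lo < 0 or hi >= params.n_snps:
            raise ValueError("sweep cluster extends outside the SNP range")
        p0[lo : hi + 1] = sw.root_freq
        sweep_members.extend(range(lo, hi + 1))

    k_pops = len(params.population_names)
    pop_freqs = np.empty((k_pops, params.n_snps))
    for i, F in enumerate(params.branch_drift):
        Fvec = np.full(params.n_snps, float(F))
        if i == 0 and selected.size:
            Fvec[selected] = F * params.selection_boost
        pop_freqs[i] = _balding_nichols(p0, Fvec, rng)

    for sw in params.sweeps:
        shift = sw.focal_freq - sw.root_freq
        pop_freqs[0, sw.center_index] = sw.focal_freq
        for j, w in enumerate(sw.flank_weights, start=1):
            pop_freqs[0, sw.center_index - j] = sw.root_freq + w * shift
            pop_freqs[0, sw.center_index + j] = sw.root_freq + w * shift

    return SimulatedPanel(
        root_freqs=p0,
        pop_freqs=pop_freqs,
        selected_loci=selected,
        sweep_members=np.asarray(sorted(set(sweep_members)), dtype=int),
        params=params,
    )


def sample_genotypes(
    panel: SimulatedPanel,
    sizes: Sequence[int] | None = None,
    seed: int = 0,
) -> GenotypeMatrix:
    """Draw diploid genotypes Binomial(2, p) per population.

    Variant coordinates are synthetic: fixed spacing on successive
    chromosomes, so positional window rules behave realistically.
    """
    params = panel.params
    sizes = tuple(params.sample_sizes if sizes is None else sizes)
    if len(sizes) != len(panel.population_names):
        raise ValueError("one sample size per population required")
    if any(n <= 0 for n in sizes):
        raise ValueError("sample sizes must be positive")
    rng = np.random.default_rng(seed)
    blocks = []
    sample_ids: list[str] = []
    pops: list[str] = []
    for name, n, freqs in zip(panel.population_names, sizes, panel.pop_freqs):
        blocks.append(rng.binomial(2, freqs[None, :].repeat(n, axis=0)).astype(np.int8))
        sample_ids.extend(f"{name}_{i:03d}" for i in range(n))
        pops.extend([name] * n)
    calls = np.vstack(blocks)
    samples = pd.DataFrame({"sample_id": sample_ids, "population": pops})
    variants = synthetic_variant_table(
        params.n_snps, spacing_bp=params.spacing_bp, snps_per_chrom=params.snps_per_chrom
    )
    return GenotypeMatrix(calls=calls, samples=samples, variants=variants)


# --------------------------------------------------------------------------
# phenotype
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenotypeParams:
    """Additive quantitative phenotype with covariates and Gaussian noise.

    The defaults emulate a diastolic blood-pressure-like trait in an elderly
    female cohort: intercept 70 mm Hg, a protective per-allele effect of
    -10 mm Hg and residual noise of 8 mm Hg.
    """

    causal_snp: str | None = None
    beta_per_allele: float = -10.0
    intercept: float = 70.0
    covariate_laws: dict = field(
        default_factory=lambda: {
            "age": (65.0, 8.0),
            "height": (158.0, 6.0),
            "weight": (60.0, 9.0),
            "dive_duration": (30.0, 8.0),
        }
    )
    covariate_effects: dict = field(
        default_factory=lambda: {
            "age": 0.25,
            "height": 0.0,
            "weight": 0.10,
            "dive_duration": 0.05,
        }
    )
    noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for name, (mean, sd) in self.covariate_laws.items():
            if sd < 0:
                raise ValueError(f"negative sd for covariate {name!r}")


def simulate_phenotype(genotypes: GenotypeMatrix, params: PhenotypeParams) -> pd.DataFrame:
    """Simulate the phenotype table (one row per sample).

    phenotype = intercept + beta * dosage + sum(effect * covariate) + noise.
    """
    rng = np.random.default_rng(params.seed)
    n = genotypes.n_samples
    table = pd.DataFrame(
        {
            "sample_id": genotypes.sample_ids,
            "population": genotypes.populations,
        }
    )
    y = np.full(n, params.intercept, dtype=float)
    for name, (mean, sd) in params.covariate_laws.items():
        table[name] = rng.normal(mean, sd, n)
        y += params.covariate_effects.get(name, 0.0) * table[name].to_numpy()
    if params.causal_snp is not None:
        dosage = genotypes.dosage(params.causal_snp)
        if np.isnan(dosage).any():
            dosage = np.nan_to_num(dosage)
        y += params.beta_per_allele * dosage
    y += rng.normal(0.0, params.noise_sd, n)
    table.insert(1, "phenotype", y)
    cols = ["sample_id", "phenotype"] + list(params.covariate_laws) + ["population"]
    return table[cols]


# --------------------------------------------------------------------------
# artifacts
# --------------------------------------------------------------------------

@dataclass
class ArtifactTruth:
    """Ground truth for injected artifacts."""

    flipped_variants: list[str]
    related_pairs: list[tuple[str, str]]   # (template, replaced)
    panel_b_samples: list[str]


def inject_artifacts(
    genotypes: GenotypeMatrix,
    n_flips: int = 0,
    n_related_pairs: int = 0,
    seed: int = 0,
    panel_b: Sequence[str] | str | None = None,
) -> tuple[GenotypeMatrix, ArtifactTruth]:
    """Inject allele-flip and relatedness artifacts, returning ground truth.

    Allele flips recode one sample subset ("panel B", by default the last
    population, playing the role of a separately genotyped reference panel)
    as ``2 - g`` at sites fixed in the realised sample, which produces the
    apparent fixed-difference signature of strand/allele coding errors.
    Related pairs overwrite one sample with a Mendelian resample of another:
    at every SNP one allele is copied from the template and one drawn from
    the population frequency (a parent-offspring pair, K0 ~ 0).
    """
    if n_flips < 0 or n_related_pairs < 0:
        raise ValueError("artifact counts must be >= 0")
    if n_flips > genotypes.n_variants:
        raise ValueError("n_flips exceeds number of variants")
    if n_related_pairs > genotypes.n_samples // 2:
        raise ValueError("n_related_pairs exceeds floor(samples / 2)")

    out = genotypes.copy()
    rng = np.random.default_rng(seed)
    pops = out.populations

    if panel_b is None:
        panel_b_ids = [s for s, p in zip(out.sample_ids, pops) if p == out.population_names()[-1]]
    elif isinstance(panel_b, str):
        panel_b_ids = [s for s, p in zip(out.sample_ids, pops) if p == panel_b]
    else:
        panel_b_ids = list(panel_b)
    b_mask = np.isin(np.array(out.sample_ids), panel_b_ids)
    if n_flips and (b_mask.all() or not b_mask.any()):
        raise ValueError("panel B must be a proper, non-empty sample subset")

    flipped: list[str] = []
    if n_flips:
        freq = out.alt_allele_frequency()
        fixed = np.flatnonzero((freq == 0.0) | (freq == 1.0))
        if fixed.size < n_flips:
            raise ValueError(
                f"only {fixed.size} sites are fixed in the sample; "
                f"cannot inject {n_flips} allele flips"
            )
        chosen = np.sort(rng.choice(fixed, size=n_flips, replace=False))
        sub = out.calls[np.ix_(b_mask, chosen)]
        flipped_calls = np.where(sub == MISSING, MISSING, 2 - sub)
        out.calls[np.ix_(b_mask, chosen)] = flipped_calls
        flipped = out.variants["id"].iloc[chosen].tolist()

    pairs: list[tuple[str, str]] = []
    if n_related_pairs:
        # pick disjoint same-population (template, victim) pairs
        avail: dict[str, list[int]] = {}
        for i, p in enumerate(pops):
            avail.setdefault(p, []).append(i)
        candidates: list[tuple[int, int]] = []
        for p, idx in avail.items():
            idx = list(rng.permutation(idx))
            while len(idx) >= 2:
                candidates.append((idx.pop(), idx.pop()))
        if len(candidates) < n_related_pairs:
            raise ValueError("not enough samples to form the requested related pairs")
        order = rng.permutation(len(candidates))[:n_related_pairs]
        for k in order:
            ti, vi = candidates[k]
            pop_mask = pops == pops[ti]
            p_hat = out.alt_allele_frequency(sample_mask=pop_mask)
            p_hat = np.nan_to_num(p_hat, nan=0.5)
            template = out.calls[ti].astype(float)
            transmitted = rng.random(out.n_variants) < template / 2.0
            other = rng.random(out.n_variants) < p_hat
            child = (transmitted.astype(np.int8) + other.astype(np.int8))
            child[template == MISSING] = MISSING
            out.calls[vi] = child
            pairs.append((out.sample_ids[ti], out.sample_ids[vi]))

    return out, ArtifactTruth(
        flipped_variants=flipped, related_pairs=pairs, panel_b_samples=panel_b_ids
    )
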