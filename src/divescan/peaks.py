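"""Candidate-signal selection on per-SNP scan statistics.

The pipeline converts a Manhattan-style table of likelihood-ratio statistics
into a short ranked candidate list: 99th-percentile outliers, a window-support
rule (an outlier must have company within +-100 kb), a local-maximum rule
(only the strongest SNP of a window survives), single-linkage collapsing of
wide peaks (low-recombination regions can span megabases), and a top-n cut.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OutlierSet",
    "Peak",
    "CandidateSet",
    "percentile_outliers",
    "window_support_filter",
    "local_maximum_filter",
    "collapse_wide_peaks",
    "top_candidates",
    "annotate_candidates",
    "read_gene_intervals",
    "run_peak_pipeline",
]

DEFAULT_WINDOW_BP = 100_000
DEFAULT_CHAIN_BP = 1_000_000


@dataclass
class OutlierSet:
    """SNPs at or above the scan's outlier threshold."""

    table: pd.DataFrame            # columns: id, chrom, pos, llr (+ extras)
    percentile_threshold: float
    saturated: bool = False        # all llrs tied at the threshold

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class Peak:
    chrom: str
    start: int
    end: int
    top_snp: str
    top_llr: float
    top_pos: int
    n_snps: int = 1
    genes: list[str] = field(default_factory=list)


@dataclass
class CandidateSet:
    peaks: list[Peak]
    n_requested: int = 10

    def __len__(self) -> int:
        return len(self.peaks)

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {
                "rank": i + 1,
                "chrom": p.chrom,
                "pos": p.top_pos,
                "id": p.top_snp,
                "llr": p.top_llr,
                "peak_start": p.start,
                "peak_end": p.end,
                "n_snps": p.n_snps,
                "genes": ";".join(p.genes) if p.genes else "intergenic",
            }
            for i, p in enumerate(self.peaks)
        ]
        return pd.DataFrame(rows)


def percentile_outliers(scan: pd.DataFrame, q: float = 0.99) -> OutlierSet:
    """SNPs with llr >= the empirical ``q``-quantile (zeros included)."""
    if scan.empty:
        raise ValueError("empty scan table")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    llr = scan["llr"].to_numpy(dtype=float)
    threshold = float(np.quantile(llr, q))
    members = scan[llr >= threshold].reset_index(drop=True)
    saturated = len(members) == len(scan)
    if saturated:
        import warnings

        warnings.warn("degenerate outlier quantile: every SNP is retained", stacklevel=2)
    return OutlierSet(table=members, percentile_threshold=threshold, saturated=saturated)


def window_support_filter(
    outliers: OutlierSet, window_bp: int = DEFAULT_WINDOW_BP
) -> OutlierSet:
    """Retain outliers with >= 1 other outlier within +-``window_bp`` (inclusive)."""
    t = outliers.table
    keep = np.zeros(len(t), dtype=bool)
    for chrom, grp in t.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        for local_i, (gi, p) in enumerate(zip(grp.index, pos)):
            near = np.abs(pos - p) <= window_bp
            near[local_i] = False
            keep[t.index.get_loc(gi)] = bool(near.any())
    return OutlierSet(
        table=t[keep].reset_index(drop=True),
        percentile_threshold=outliers.percentile_threshold,
        saturated=outliers.saturated,
    )


def local_maximum_filter(
    outliers: OutlierSet, window_bp: int = DEFAULT_WINDOW_BP
) -> OutlierSet:
    """Retain outliers that are strict local maxima within +-``window_bp``.

    An exact llr tie inside a window is resolved deterministically: the
    lower-position SNP survives.
    """
    t = outliers.table
    keep = np.zeros(len(t), dtype=bool)
    for chrom, grp in t.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        llr = grp["llr"].to_numpy()
        for local_i, gi in enumerate(grp.index):
            near = np.abs(pos - pos[local_i]) <= window_bp
            near[local_i] = False
            others_llr = llr[near]
            others_pos = pos[near]
            beaten = (others_llr > llr[local_i]) | (
                (others_llr == llr[local_i]) & (others_pos < pos[local_i])
            )
            keep[t.index.get_loc(gi)] = not bool(beaten.any())
    return OutlierSet(
        table=t[keep].reset_index(drop=True),
        percentile_threshold=outliers.percentile_threshold,
        saturated=outliers.saturated,
    )


def collapse_wide_peaks(
    outliers: OutlierSet, chain_bp: int = DEFAULT_CHAIN_BP
) -> list[Peak]:
    """Single-linkage chaining: consecutive SNPs within ``chain_bp`` on one
    chromosome form one Peak represented by its strongest SNP."""
    t = outliers.table.sort_values(["chrom", "pos"], kind="stable")
    peaks: list[Peak] = []
    for chrom, grp in t.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        llr = grp["llr"].to_numpy()
        ids = grp["id"].to_numpy()
        start = 0
        for i in range(1, len(grp) + 1):
            if i == len(grp) or pos[i] - pos[i - 1] > chain_bp:
                seg = slice(start, i)
                top_local = int(np.argmax(llr[seg])) + start
                peaks.append(
                    Peak(
                        chrom=chrom,
                        start=int(pos[start]),
                        end=int(pos[i - 1]),
                        top_snp=str(ids[top_local]),
                        top_llr=float(llr[top_local]),
                        top_pos=int(pos[top_local]),
                        n_snps=i - start,
                    )
                )
                start = i
    return peaks


def top_candidates(peaks: list[Peak], n: int = 10) -> CandidateSet:
    """Top ``n`` peaks by llr; ties break by (chromosome, position)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ordered = sorted(peaks, key=lambda p: (-p.top_llr, p.chrom, p.top_pos))
    return CandidateSet(peaks=ordered[:n], n_requested=n)


# -------------------------------------------------------------- annotation

def read_gene_intervals(gff_path: str) -> pd.DataFrame:
    """Gene intervals (1-based inclusive) from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(
        gff_path, dbfn=":memory:", force=True, keep_order=True, merge_strategy="merge"
    )
    rows = []
    for gene in db.features_of_type("gene"):
        name = gene.attributes.get("Name", gene.attributes.get("ID", [gene.id]))[0]
        rows.append({"chrom": gene.seqid, "start": gene.start, "end": gene.end, "name": name})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def annotate_candidates(candidates: CandidateSet, genes: pd.DataFrame) -> CandidateSet:
    """Label each candidate top SNP with every overlapping gene (inclusive
    1-based interval convention); unannotated SNPs are intergenic."""
    for col in ("chrom", "start", "end", "name"):
        if col not in genes.columns:
            raise ValueError(f"gene table lacks column {col!r}")
    if (genes["end"] < genes["start"]).any():
        raise ValueError("malformed gene intervals: end < start")
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for chrom, grp in genes.groupby("chrom", sort=False):
        tree = IntervalTree()
        for _, g in grp.iterrows():
            tree.addi(int(g["start"]), int(g["end"]) + 1, g["name"])  # half-open store
        trees[chrom] = tree
    for peak in candidates.peaks:
        tree = trees.get(peak.chrom)
        hits = sorted(iv.data for iv in tree[peak.top_pos]) if tree is not None else []
        peak.genes = hits
    return candidates


def run_peak_pipeline(
    scan: pd.DataFrame,
    q: float = 0.99,
    window_bp: int = DEFAULT_WINDOW_BP,
    chain_bp: int = DEFAULT_CHAIN_BP,
    n: int = 10,
    genes: pd.DataFrame | None = None,
) -> CandidateSet:
    """percentile -> window support -> local maximum -> collapse -> top n."""
    out = percentile_outliers(scan, q=q)
    out = window_support_filter(out, window_bp=window_bp)
    out = local_maximum_filter(out, window_bp=window_bp)
    peaks = collapse_wide_peaks(out, chain_bp=chain_bp)
    cand = top_candidates(peaks, n=n)
    if genes is not None:
        cand = annotate_candidates(cand, genes)
    return cand
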