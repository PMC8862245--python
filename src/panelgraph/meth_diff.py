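"""CpG-island differential methylation from per-read log-likelihood ratios.

Per-read LLRs (methylated over unmethylated, natural log, as emitted by
nanopore callers) are aggregated to per-position sample medians; each CpG
island with sufficient coverage is tested across samples with a
Kruskal-Wallis test; p-values are adjusted with Benjamini-Hochberg. Island
state per sample follows the +/-1 LLR ambiguity band.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SiteSummary",
    "IslandTest",
    "read_meth_calls",
    "read_islands_bed",
    "aggregate_sites",
    "test_island",
    "test_islands",
    "bh_adjust",
    "apply_fdr",
    "island_state",
    "tss_distance",
    "tss_distance_summary",
    "dmr_report",
]

AMBIGUITY_BAND = 1.0  # |median llr| below this is ambiguous

CALL_COLUMNS = ["chrom", "position", "read", "log_lik_ratio"]


@dataclass(frozen=True)
class SiteSummary:
    sample: str
    chrom: str
    position: int
    n_reads: int
    median_llr: float


@dataclass
class IslandTest:
    chrom: str
    start: int
    end: int
    samples: tuple[str, ...]
    site_medians: dict[str, np.ndarray]
    island_medians: dict[str, float]
    statistic: float | None
    pvalue: float | None
    qvalue: float | None = None
    significant: bool | None = None
    skipped_reason: str | None = None

    @property
    def tested(self) -> bool:
        return self.pvalue is not None

    def states(self, band: float = AMBIGUITY_BAND) -> dict[str, str]:
        return {s: island_state(m, band) for s, m in self.island_medians.items()}


def island_state(median_llr: float, band: float = AMBIGUITY_BAND) -> str:
    if median_llr >= band:
        return "methylated"
    if median_llr <= -band:
        return "unmethylated"
    return "ambiguous"


# ---------------------------------------------------------------------------
# input plumbing


def read_meth_calls(path: str | Path, sample: str) -> pd.DataFrame:
    """Read a per-read call TSV with columns chrom, position, read, log_lik_ratio."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CALL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df[CALL_COLUMNS].copy()
    if not np.isfinite(df["log_lik_ratio"]).all():
        raise ValueError(f"{path}: non-finite log_lik_ratio values")
    df["sample"] = sample
    return df


def read_islands_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2], names=["chrom", "start", "end"]
    )
    return df


# ---------------------------------------------------------------------------
# aggregation


def aggregate_sites(calls: pd.DataFrame, min_reads: int = 5) -> pd.DataFrame:
    """Median LLR per (sample, chrom, position); positions with fewer than
    ``min_reads`` reads are dropped.

    Returns a frame with columns sample, chrom, position, n_reads, median_llr.
    """
    grouped = (
        calls.groupby(["sample", "chrom", "position"], sort=True)["log_lik_ratio"]
        .agg(n_reads="size", median_llr="median")
        .reset_index()
    )
    return grouped[grouped["n_reads"] >= min_reads].reset_index(drop=True)


# ---------------------------------------------------------------------------
# testing


def _kruskal(groups: list[np.ndarray]) -> tuple[float, float]:
    flat = np.concatenate(groups)
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def test_island(
    chrom: str,
    start: int,
    end: int,
    sites: pd.DataFrame,
    min_sites: int = 3,
    min_samples: int = 4,
) -> IslandTest:
    """Kruskal-Wallis across samples of the site-median LLRs inside one island.

    Samples contributing fewer than ``min_sites`` site medians are excluded;
    the island is skipped (reason recorded) when fewer than ``min_samples``
    remain, or fewer than 2 groups are available.
    """
    inside = sites[
        (sites["chrom"] == chrom)
        & (sites["position"] >= start)
        & (sites["position"] < end)
    ]
    vectors: dict[str, np.ndarray] = {}
    for sample, sub in inside.groupby("sample", sort=True):
        vals = sub["median_llr"].to_numpy(dtype=float)
        if len(vals) >= min_sites:
            vectors[sample] = vals
    medians = {s: float(np.median(v)) for s, v in vectors.items()}
    base = dict(
        chrom=chrom,
        start=start,
        end=end,
        samples=tuple(vectors),
        site_medians=vectors,
        island_medians=medians,
    )
    if len(vectors) < max(min_samples, 2):
        return IslandTest(
            **base, statistic=None, pvalue=None,
            skipped_reason=f"only {len(vectors)} sample(s) with >= {min_sites} sites",
        )
    h, p = _kruskal([vectors[s] for s in sorted(vectors)])
    return IslandTest(**base, statistic=h, pvalue=p)


def test_islands(
    islands: pd.DataFrame,
    sites: pd.DataFrame,
    min_sites: int = 3,
    min_samples: int = 4,
) -> list[IslandTest]:
    """Vectorised island sweep: assigns sites to islands then tests each island."""
    out: list[IslandTest] = []
    for chrom, isl in islands.groupby("chrom", sort=True):
        chrom_sites = sites[sites["chrom"] == chrom].sort_values("position", kind="stable")
        positions = chrom_sites["position"].to_numpy()
        for row in isl.sort_values(["start", "end"]).itertuples(index=False):
            lo = int(np.searchsorted(positions, int(row.start), side="left"))
            hi = int(np.searchsorted(positions, int(row.end), side="left"))
            out.append(
                test_island(
                    chrom, int(row.start), int(row.end), chrom_sites.iloc[lo:hi],
                    min_sites=min_sites, min_samples=min_samples,
                )
            )
    return out


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: q_(i) = min_{j>=i} m p_(j) / j, clipped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0,1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def apply_fdr(tests: Sequence[IslandTest], alpha: float = 0.01) -> None:
    """Attach BH q-values and significance flags in place (tested islands only)."""
    tested = [t for t in tests if t.tested]
    if not tested:
        return
    q = bh_adjust([t.pvalue for t in tested])
    for t, qv in zip(tested, q):
        t.qvalue = float(qv)
        t.significant = bool(qv <= alpha)


# ---------------------------------------------------------------------------
# summaries


def tss_distance(start: int, end: int, tss_positions: np.ndarray) -> int:
    """Distance from an island interval to the closest TSS (0 when inside)."""
    if tss_positions.size == 0:
        raise ValueError("no TSS positions supplied")
    left = start - tss_positions  # >0 when tss left of island
    right = tss_positions - (end - 1)
    d = np.maximum.reduce([left, right, np.zeros_like(left)])
    return int(d.min())


def tss_distance_summary(
    tests: Sequence[IslandTest],
    genes: Sequence,
) -> pd.DataFrame:
    """Per-island distance to the closest gene TSS, with significance labels.

    ``genes`` are :class:`~panelgraph.core_genes.GeneModel` objects (or any
    objects with ``stable_name`` and ``tss``). Returns a frame with columns
    chrom, start, end, significant, tss_distance; a rank-sum comparison of
    the two distance distributions is attached as ``df.attrs``.
    """
    tss_by_chrom: dict[str, list[int]] = {}
    for gene in genes:
        tss_by_chrom.setdefault(gene.stable_name, []).append(gene.tss)
    tss_arr = {c: np.array(sorted(v)) for c, v in tss_by_chrom.items()}
    rows = []
    for t in tests:
        if not t.tested or t.chrom not in tss_arr:
            continue
        rows.append(
            {
                "chrom": t.chrom,
                "start": t.start,
                "end": t.end,
                "significant": bool(t.significant),
                "tss_distance": tss_distance(t.start, t.end, tss_arr[t.chrom]),
            }
        )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "significant", "tss_distance"])
    sig = df.loc[df["significant"], "tss_distance"]
    non = df.loc[~df["significant"], "tss_distance"]
    if len(sig) and len(non):
        stat, p = stats.mannwhitneyu(sig, non, alternative="two-sided")
        df.attrs["ranksum_stat"] = float(stat)
        df.attrs["ranksum_p"] = float(p)
        df.attrs["median_significant"] = float(sig.median())
        df.attrs["median_nonsignificant"] = float(non.median())
    return df


def dmr_report(
    tests: Sequence[IslandTest],
    alpha: float = 0.01,
    band: float = AMBIGUITY_BAND,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Significant-island table plus the islands x samples clustering matrix.

    The matrix holds per-sample island median LLRs for significant islands
    (heatmap convention -3..3 with |llr| < ``band`` ambiguous).
    """
    sig = [t for t in tests if t.tested and t.qvalue is not None and t.qvalue <= alpha]
    rows = []
    for t in sig:
        row = {
            "chrom": t.chrom,
            "start": t.start,
            "end": t.end,
            "statistic": t.statistic,
            "pvalue": t.pvalue,
            "qvalue": t.qvalue,
        }
        for s, m in t.island_medians.items():
            row[f"median_{s}"] = m
            row[f"state_{s}"] = island_state(m, band)
        rows.append(row)
    table = pd.DataFrame(rows)
    samples = sorted({s for t in sig for s in t.island_medians})
    matrix = pd.DataFrame(
        [[t.island_medians.get(s, np.nan) for s in samples] for t in sig],
        index=[f"{t.chrom}:{t.start}-{t.end}" for t in sig],
        columns=samples,
    )
    matrix.index.name = "island"
    return table, matrix
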