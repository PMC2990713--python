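"""Interval algebra over CNVRs and genomic features.

Covers the downstream accounting: merging annotation intervals to
non-redundant form (to avoid double counting), total overlap length
between interval sets, the gene/intergenic coverage table, gene-overlap
identification (any shared bp counts), and the random-interval
permutation test that asks whether the observed CNVR/feature overlap is
smaller (depletion) or larger (enrichment) than for length-matched
intervals thrown uniformly on the genome.

Merged interval sets are kept as sorted disjoint arrays per chromosome;
overlap queries use prefix-sum coverage, O(log n) per query interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cghcnv.errors import PlacementError, StructuralError
from cghcnv.genome import GenomeModel


@dataclass
class IntervalSet:
    """Intervals (chrom, start, end[, id]); 0-based half-open."""

    intervals: pd.DataFrame
    merged: bool = False

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end"}
        if not required <= set(self.intervals.columns):
            raise StructuralError(f"interval table needs columns {required}")
        if len(self.intervals) and (self.intervals["end"] <= self.intervals["start"]).any():
            raise StructuralError("intervals must have end > start")

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def total_length(self) -> int:
        return int((self.intervals["end"] - self.intervals["start"]).sum())

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IntervalSet":
        return cls(df[[c for c in ("chrom", "start", "end", "id") if c in df.columns]].copy())


def merge_intervals(iset: IntervalSet) -> IntervalSet:
    """Collapse self-overlapping and book-ended intervals per chromosome."""
    df = iset.intervals
    rows = []
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cs, ce = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            if s > ce:
                rows.append((chrom, cs, ce))
                cs, ce = int(s), int(e)
            else:
                ce = max(ce, int(e))
        rows.append((chrom, cs, ce))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return IntervalSet(out, merged=True)


class _Coverage:
    """Prefix-sum coverage of a merged interval set, per chromosome."""

    def __init__(self, merged: IntervalSet):
        if not merged.merged:
            merged = merge_intervals(merged)
        self.per_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in merged.intervals.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy(np.int64)
            ends = sub["end"].to_numpy(np.int64)
            prefix = np.concatenate([[0], np.cumsum(ends - starts)])
            self.per_chrom[str(chrom)] = (starts, ends, prefix)

    def covered_before(self, chrom: str, x: np.ndarray) -> np.ndarray:
        """Total covered bp in [0, x) for each x."""
        if chrom not in self.per_chrom:
            return np.zeros(len(x), dtype=np.int64)
        starts, ends, prefix = self.per_chrom[chrom]
        i = np.searchsorted(starts, x, side="right")
        cov = prefix[i].astype(np.int64)
        has_prev = i > 0
        prev = np.maximum(i - 1, 0)
        trunc = np.clip(ends[prev] - x, 0, (ends - starts)[prev])
        cov -= np.where(has_prev, trunc, 0)
        return cov

    def overlap(self, chrom: str, start: np.ndarray, end: np.ndarray) -> np.ndarray:
        return self.covered_before(chrom, end) - self.covered_before(chrom, start)


def overlap_length(a: IntervalSet, b: IntervalSet) -> int:
    """Total bp of intersection between two merged interval sets."""
    am = a if a.merged else merge_intervals(a)
    cov = _Coverage(b if b.merged else merge_intervals(b))
    total = 0
    for chrom, sub in am.intervals.groupby("chrom", sort=False):
        total += int(
            cov.overlap(
                str(chrom), sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64)
            ).sum()
        )
    return total


def coverage_table(
    cnvrs: pd.DataFrame, genes: IntervalSet, genome: GenomeModel
) -> pd.DataFrame:
    """Gene / intergenic constitution of CNVRs and of the whole genome.

    One row per CNVR status plus a Total row and a Genome row, with bp
    lengths and percentages (gene overlap vs intergenic remainder).
    """
    genes_m = genes if genes.merged else merge_intervals(genes)
    rows = []
    pieces = []
    for status in ("gain", "loss"):
        sub = cnvrs[cnvrs["status"] == status]
        iset = IntervalSet.from_frame(sub[["chrom", "start", "end"]]) if len(sub) else None
        total = int((sub["end"] - sub["start"]).sum()) if len(sub) else 0
        gene_bp = overlap_length(iset, genes_m) if iset is not None and len(sub) else 0
        rows.append((status.capitalize(), total, gene_bp, total - gene_bp))
        pieces.append((total, gene_bp))
    total = sum(p[0] for p in pieces)
    gene_bp = sum(p[1] for p in pieces)
    rows.append(("Total", total, gene_bp, total - gene_bp))
    g_total = genome.total_length
    g_gene = genes_m.total_length
    rows.append(("Genome", g_total, g_gene, g_total - g_gene))
    out = pd.DataFrame(rows, columns=["region", "total_bp", "gene_bp", "intergenic_bp"])
    with np.errstate(invalid="ignore"):
        out["gene_pct"] = (100.0 * out["gene_bp"] / out["total_bp"]).round(2)
        out["intergenic_pct"] = (100.0 * out["intergenic_bp"] / out["total_bp"]).round(2)
    return out


def genes_overlapping(cnvrs: pd.DataFrame, genes: pd.DataFrame) -> dict[str, list[str]]:
    """Gene ids overlapping >= 1 bp of a CNVR, per status.

    A gene may appear under both statuses.  Half-open coordinates: a gene
    ending exactly where a CNVR starts does not overlap.
    """
    out: dict[str, list[str]] = {}
    for status in ("gain", "loss"):
        sub = cnvrs[cnvrs["status"] == status]
        hits: set[str] = set()
        for chrom, regions in sub.groupby("chrom", sort=False):
            g = genes[genes["chrom"] == chrom]
            if g.empty:
                continue
            gs = g["start"].to_numpy()
            ge = g["end"].to_numpy()
            for row in regions.itertuples():
                sel = (gs < row.end) & (ge > row.start)
                hits.update(g["id"].to_numpy()[sel])
        out[status] = sorted(hits)
    return out


@dataclass
class OverlapResult:
    """Outcome of the random-interval permutation test."""

    observed: int
    null_overlaps: np.ndarray
    tail: str
    n_rounds: int
    seed: int
    p_value: float = field(init=False)
    expected: float = field(init=False)
    null_sd: float = field(init=False)
    z: float = field(init=False)

    def __post_init__(self) -> None:
        null = np.asarray(self.null_overlaps, dtype=float)
        self.expected = float(null.mean())
        self.null_sd = float(null.std(ddof=1)) if len(null) > 1 else float("nan")
        if self.tail == "depletion":
            k = int((null <= self.observed).sum())
        elif self.tail == "enrichment":
            k = int((null >= self.observed).sum())
        else:
            raise StructuralError(f"unknown tail {self.tail!r}")
        self.p_value = (k + 1) / (len(null) + 1)
        self.z = (
            (self.observed - self.expected) / self.null_sd if self.null_sd > 0 else float("nan")
        )

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "expected": self.expected,
            "sd": self.null_sd,
            "z": self.z,
            "p": self.p_value,
            "tail": self.tail,
            "n_rounds": self.n_rounds,
            "seed": self.seed,
        }


def random_interval_test(
    query: IntervalSet,
    features: IntervalSet,
    genome: GenomeModel,
    n_rounds: int = 1000,
    tail: str = "depletion",
    seed: int = 0,
) -> OverlapResult:
    """Length-matched random-interval null for query/feature overlap.

    Each round places ``len(query)`` intervals with the query's exact
    lengths uniformly at random: a chromosome is chosen with probability
    proportional to its number of valid start positions (length - interval
    length + 1), the start uniformly among them; placed intervals may
    overlap one another and their summed per-interval feature overlap is
    the round's statistic.  The empirical p-value uses the (k+1)/(n+1)
    estimator, so it is never exactly zero.
    """
    lengths = (query.intervals["end"] - query.intervals["start"]).to_numpy(np.int64)
    chrom_names = genome.chrom_order()
    chrom_len = np.array([genome.chromosomes[c] for c in chrom_names], dtype=np.int64)
    cov = _Coverage(features)
    rng = np.random.default_rng(seed)

    observed = 0
    for chrom, sub in query.intervals.groupby("chrom", sort=False):
        observed += int(
            cov.overlap(
                str(chrom), sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64)
            ).sum()
        )

    null = np.zeros(n_rounds, dtype=np.int64)
    for ell in lengths:
        valid = np.maximum(chrom_len - ell + 1, 0)
        if valid.sum() == 0:
            raise PlacementError(f"interval of {ell} bp fits on no chromosome")
        probs = np.cumsum(valid / valid.sum())
        u = rng.random(n_rounds)
        cidx = np.searchsorted(probs, u, side="right")
        starts = (rng.random(n_rounds) * valid[cidx]).astype(np.int64)
        for c in np.unique(cidx):
            sel = cidx == c
            s = starts[sel]
            null[sel] += cov.overlap(chrom_names[c], s, s + ell)
    return OverlapResult(
        observed=observed, null_overlaps=null, tail=tail, n_rounds=n_rounds, seed=seed
    )
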