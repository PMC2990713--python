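"""CNV-region calling from smoothed M values and cross-sample merging.

A core is a maximal run of at least ``min_probes`` consecutive probes
whose smoothed M values all exceed +``threshold`` (gain) or all fall
below -``threshold`` (loss).  The threshold 0.5 sits just under
log2(3/2) ~ 0.585, the expected ratio when one of the two alleles is
duplicated.  Each core is extended by ``flank`` bp on both sides
(about half the median inter-probe spacing, the reach of a single
probe) and clamped to the chromosome.  Per-sample regions of the same
status that touch after extension are merged.

The non-redundant set is the status-stratified union across samples:
overlapping or book-ended regions merge, supporting samples accumulate,
and regions are named ``cnv.<status>.<k>`` in genomic order.

Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from cghcnv.errors import StructuralError
from cghcnv.genome import GenomeModel

CNVR_COLUMNS = [
    "chrom",
    "start",
    "end",
    "status",
    "core_start",
    "core_end",
    "sample_id",
    "n_probes",
    "mean_m",
]


def call_cores(
    probes: pd.DataFrame,
    sample: str,
    genome: GenomeModel,
    threshold: float = 0.5,
    min_probes: int = 3,
    flank: int = 5_000,
    max_gap: int | None = None,
) -> pd.DataFrame:
    """Call per-sample CNVRs from a probe table with a ``smoothed`` column.

    ``probes`` must be ordered by (chrom, start).  ``max_gap`` optionally
    breaks runs at genomic gaps larger than the given bp (default: no
    maximum-gap rule).  Returns a CNVR table (CNVR_COLUMNS).
    """
    required = {"chrom", "start", "end", "smoothed"}
    if not required <= set(probes.columns):
        raise StructuralError(f"probe table needs columns {required}")
    rows = []
    for chrom, sub in probes.groupby("chrom", sort=False, observed=True):
        starts = sub["start"].to_numpy()
        if (np.diff(starts) < 0).any():
            raise StructuralError(f"probes not sorted by position on {chrom!r}")
        L = genome.chromosomes[str(chrom)]
        ends = sub["end"].to_numpy()
        m = sub["smoothed"].to_numpy(float)
        n = len(starts)
        breaks = np.zeros(n, dtype=bool)
        if max_gap is not None and n > 1:
            breaks[1:] = (starts[1:] - ends[:-1]) > max_gap
        for status, sign in (("gain", 1.0), ("loss", -1.0)):
            hot = sign * m > threshold
            k = 0
            while k < n:
                if not hot[k]:
                    k += 1
                    continue
                j = k + 1
                while j < n and hot[j] and not breaks[j]:
                    j += 1
                if j - k >= min_probes:
                    core_s = int(starts[k])
                    core_e = int(ends[j - 1])
                    rows.append(
                        (
                            str(chrom),
                            max(0, core_s - flank),
                            min(L, core_e + flank),
                            status,
                            core_s,
                            core_e,
                            sample,
                            j - k,
                            float(m[k:j].mean()),
                        )
                    )
                k = j
    df = pd.DataFrame(rows, columns=CNVR_COLUMNS)
    return _merge_touching_same_sample(df)


def _merge_touching_same_sample(df: pd.DataFrame) -> pd.DataFrame:
    """Merge same-status regions of one sample that touch after extension."""
    if df.empty:
        return df
    out = []
    for (chrom, status, sample), sub in df.groupby(
        ["chrom", "status", "sample_id"], sort=False
    ):
        sub = sub.sort_values("start")
        cur = None
        for row in sub.itertuples():
            if cur is None or row.start > cur["end"]:
                if cur is not None:
                    out.append(cur)
                cur = {
                    "chrom": chrom, "start": row.start, "end": row.end, "status": status,
                    "core_start": row.core_start, "core_end": row.core_end,
                    "sample_id": sample, "n_probes": row.n_probes,
                    "_msum": row.mean_m * row.n_probes,
                }
            else:
                cur["end"] = max(cur["end"], row.end)
                cur["core_end"] = max(cur["core_end"], row.core_end)
                cur["n_probes"] += row.n_probes
                cur["_msum"] += row.mean_m * row.n_probes
        if cur is not None:
            out.append(cur)
    res = pd.DataFrame(out)
    res["mean_m"] = res.pop("_msum") / res["n_probes"]
    res = res.sort_values(["chrom", "start"]).reset_index(drop=True)
    return res[CNVR_COLUMNS]


def merge_to_nonredundant(
    per_sample: list[pd.DataFrame], genome: GenomeModel
) -> pd.DataFrame:
    """Status-stratified union of per-sample CNVR sets.

    Overlapping or book-ended regions of the same status merge across
    samples; supporting samples are the union of contributors; names
    ``cnv.<status>.<k>`` are assigned in genomic order per status.
    Per-sample core mean M values are kept as a ``sample:mean`` summary.
    """
    if not per_sample:
        raise StructuralError("need at least one per-sample CNVR set")
    allr = pd.concat(per_sample, ignore_index=True)
    chrom_order = {c: i for i, c in enumerate(genome.chrom_order())}
    out = []
    for status in ("gain", "loss"):
        sub = allr[allr["status"] == status].copy()
        if sub.empty:
            continue
        sub["_c"] = sub["chrom"].map(chrom_order)
        sub = sub.sort_values(["_c", "start"])
        cur = None
        merged = []
        for row in sub.itertuples():
            if cur is None or row.chrom != cur["chrom"] or row.start > cur["end"]:
                if cur is not None:
                    merged.append(cur)
                cur = {
                    "chrom": row.chrom, "start": row.start, "end": row.end,
                    "status": status,
                    "core_start": row.core_start, "core_end": row.core_end,
                    "samples": {row.sample_id: [row.mean_m]},
                }
            else:
                cur["end"] = max(cur["end"], row.end)
                cur["core_start"] = min(cur["core_start"], row.core_start)
                cur["core_end"] = max(cur["core_end"], row.core_end)
                cur.setdefault("samples", {}).setdefault(row.sample_id, []).append(row.mean_m)
        if cur is not None:
            merged.append(cur)
        for k, reg in enumerate(merged, start=1):
            samples = reg.pop("samples")
            reg["name"] = f"cnv.{status}.{k}"
            reg["support"] = ",".join(sorted(samples))
            reg["n_support"] = len(samples)
            reg["mean_m_by_sample"] = ";".join(
                f"{s}:{np.mean(v):.4f}" for s, v in sorted(samples.items())
            )
            out.append(reg)
    res = pd.DataFrame(
        out,
        columns=[
            "chrom", "start", "end", "status", "core_start", "core_end",
            "name", "support", "n_support", "mean_m_by_sample",
        ],
    )
    res["_c"] = res["chrom"].map(chrom_order)
    res = res.sort_values(["_c", "start"]).drop(columns="_c").reset_index(drop=True)
    return res


def write_bed(cnvrs: pd.DataFrame, path, score_from: str | None = None) -> None:
    """Write CNVRs as BED6+ (name, capped score, strand '.', extra cols)."""
    bed = cnvrs.copy()
    if "name" not in bed.columns:
        bed["name"] = [
            f"cnv.{s}.{i}" for i, s in enumerate(bed["status"], start=1)
        ]
    if score_from and score_from in bed.columns:
        score = (1000 * bed[score_from].abs()).clip(upper=1000).round().astype(int)
    else:
        score = 0
    cols = pd.DataFrame(
        {
            "chrom": bed["chrom"],
            "start": bed["start"],
            "end": bed["end"],
            "name": bed["name"],
            "score": score,
            "strand": ".",
            "status": bed["status"],
        }
    )
    for extra in ("support", "n_support", "mean_m_by_sample", "sample_id", "mean_m"):
        if extra in bed.columns:
            cols[extra] = bed[extra]
    cols.to_csv(path, sep="\t", header=False, index=False, float_format="%.4f")
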