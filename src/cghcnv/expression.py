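"""Expression re-analysis: probeset collapsing, per-gene t-tests with BH
FDR, and CNV-vs-expression direction consistency calls.

Mirrors the companion expression workflow: genes measured by several
probesets are collapsed to the probeset most often attaining the gene's
maximum intensity across samples (ties averaged sample-wise); per-gene
two-group t-tests on log2 intensities are BH-adjusted with an FDR
threshold of 0.2 (so >80% of called genes are expected to be truly
differential); and genes in called CNVRs are labeled consistent when the
copy-number direction matches the expression direction (gain & up, or
loss & down), inconsistent when opposite, untested when not significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from cghcnv.errors import CghCnvError, StructuralError
from cghcnv.enrich import bh_adjust


@dataclass
class ExpressionMatrix:
    """Probeset x sample intensities (linear scale) with metadata."""

    intensities: pd.DataFrame          # probesets x samples, > 0
    probeset_to_gene: pd.Series        # probeset id -> gene id (<=1 gene each)
    groups: pd.Series                  # sample id -> 'test' | 'control'

    def __post_init__(self) -> None:
        if (self.intensities.to_numpy() <= 0).any():
            raise StructuralError("intensities must be positive")
        unknown = set(self.intensities.columns) - set(self.groups.index)
        if unknown:
            raise StructuralError(f"samples without group labels: {unknown}")


def read_expression_tsv(path, mapping_path) -> ExpressionMatrix:
    """Read a probeset x sample intensity table with a two-line header
    (sample ids, then group labels) plus a two-column probeset->gene map."""
    with open(path) as fh:
        samples = fh.readline().rstrip("\n").split("\t")[1:]
        labels = fh.readline().rstrip("\n").split("\t")[1:]
        X = pd.read_csv(fh, sep="\t", header=None, index_col=0)
    X.columns = samples
    X.index.name = "probeset"
    mapping = pd.read_csv(
        mapping_path, sep="\t", header=None, names=["probeset", "gene"], dtype=str
    ).set_index("probeset")["gene"]
    return ExpressionMatrix(
        intensities=X,
        probeset_to_gene=mapping,
        groups=pd.Series(labels, index=samples),
    )


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    with open(path, "w") as fh:
        samples = list(matrix.intensities.columns)
        fh.write("probeset\t" + "\t".join(samples) + "\n")
        fh.write("group\t" + "\t".join(matrix.groups[s] for s in samples) + "\n")
        matrix.intensities.to_csv(fh, sep="\t", header=False, float_format="%.6f")


def collapse_probesets(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Collapse to one row per gene by the most-often-maximal rule.

    For each gene, count per probeset the samples in which it attains the
    gene's maximum intensity (ties in a sample credit every attaining
    probeset); keep the probeset(s) with the top count and average them
    sample-wise if more than one remains.  Invariant to probeset row
    order.
    """
    X = matrix.intensities
    gene_of = matrix.probeset_to_gene.reindex(X.index).dropna()
    rows = {}
    for gene, idx in sorted(gene_of.groupby(gene_of).groups.items()):
        sub = X.loc[sorted(idx)]
        if len(sub) == 1:
            rows[gene] = sub.iloc[0]
            continue
        at_max = sub.eq(sub.max(axis=0), axis=1)
        counts = at_max.sum(axis=1)
        winners = counts[counts == counts.max()].index
        rows[gene] = sub.loc[winners].mean(axis=0)
    out = pd.DataFrame(rows).T
    out.index.name = "gene"
    out.columns = X.columns
    return out


def de_test(
    gene_matrix: pd.DataFrame,
    groups: pd.Series,
    fdr_threshold: float = 0.2,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-gene two-group t-test on log2 intensities.

    Welch's unequal-variance test by default (``equal_var=True`` for the
    pooled-variance form).  log2 fold change is mean(log2 test) -
    mean(log2 control).  Returns gene, log2_fc, raw_p, fdr, direction
    ('up'/'down' when fdr <= threshold, else 'ns').
    """
    test_cols = [c for c in gene_matrix.columns if groups[c] == "test"]
    ctrl_cols = [c for c in gene_matrix.columns if groups[c] == "control"]
    if len(test_cols) < 2 or len(ctrl_cols) < 2:
        raise CghCnvError("each group needs at least 2 samples")
    lt = np.log2(gene_matrix[test_cols].to_numpy(float))
    lc = np.log2(gene_matrix[ctrl_cols].to_numpy(float))
    tstat, p = stats.ttest_ind(lt, lc, axis=1, equal_var=equal_var)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance identical groups
    lfc = lt.mean(axis=1) - lc.mean(axis=1)
    fdr = bh_adjust(p)
    direction = np.where(
        fdr <= fdr_threshold, np.where(lfc > 0, "up", "down"), "ns"
    )
    return pd.DataFrame(
        {
            "gene": gene_matrix.index,
            "log2_fc": lfc,
            "t": tstat,
            "raw_p": p,
            "fdr": fdr,
            "direction": direction,
        }
    ).set_index("gene")


def consistency_call(
    cnv_status: dict[str, str], de: pd.DataFrame
) -> pd.DataFrame:
    """Label each CNV gene consistent / inconsistent / untested.

    Consistent: gain & up or loss & down; inconsistent: opposite
    directions; untested: not differentially expressed (or not measured).
    """
    rows = []
    for gene, status in sorted(cnv_status.items()):
        if gene in de.index:
            direction = de.loc[gene, "direction"]
        else:
            direction = "ns"
        if direction == "ns":
            label = "untested"
        elif (status == "gain") == (direction == "up"):
            label = "consistent"
        else:
            label = "inconsistent"
        rows.append((gene, status, direction, label))
    return pd.DataFrame(
        rows, columns=["gene", "cnv_status", "direction", "label"]
    ).set_index("gene")


def mirna_signal_summary(
    fg: pd.DataFrame, bg: pd.DataFrame, groups: pd.Series
) -> pd.DataFrame:
    """Mean background-subtracted signal per probe per group.

    The descriptive summary used for single-channel miRNA arrays: no
    statistics, just mean foreground minus mean background by group.
    """
    out = {}
    for group in sorted(groups.unique()):
        cols = groups[groups == group].index
        out[group] = fg[cols].mean(axis=1) - bg[cols].mean(axis=1)
    return pd.DataFrame(out)
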