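"""Per-spot dye-bias modeling, correction, and the clustering diagnostic.

Each spot has one oriented M value per array.  With all arrays comparing
the same test-vs-reference contrast, the model per spot is

    M_i = alpha * GkWis_i + beta * Dye_i + e_i

where GkWis_i = 1 on every array (the genomic difference between the two
strains), Dye_i = +1 on forward and -1 on reverse hybridizations (the
spot-specific dye bias), and e_i collects individual differences and
random error.  Ordinary least squares gives alpha and beta; with a
balanced forward/reverse design alpha is the grand mean and beta is half
the forward-minus-reverse mean difference.  Correction subtracts
beta * Dye_i.  An ordinary t-test on beta (df = n - 2) flags spots with
significant dye bias; Ward/Euclidean hierarchical clustering of the
arrays before and after correction is the standard visual diagnostic
(before correction chips cluster by dye orientation, after correction
dye-swap pairs rejoin).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import t as t_dist

from cghcnv.errors import StructuralError
from cghcnv.simulate import ChipLayout


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Check and normalize an array design table.

    Expects columns array_id, sample_id, orientation; adds dye (+1/-1)
    and gkwis (1) codes.
    """
    required = {"array_id", "sample_id", "orientation"}
    missing = required - set(design.columns)
    if missing:
        raise StructuralError(f"design missing columns {missing}")
    if not design["orientation"].isin(["forward", "reverse"]).all():
        raise StructuralError("orientation must be forward or reverse")
    out = design.copy()
    out["dye"] = np.where(out["orientation"] == "forward", 1, -1)
    out["gkwis"] = 1
    if not {1, -1} <= set(out["dye"]):
        raise StructuralError("design needs at least one forward and one reverse array")
    return out


def fit_dye_model(m_table: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Per-spot OLS fit of the two-regressor dye model.

    ``m_table``: oriented M values, probes x arrays (columns = array ids).
    Probes with missing values are fitted on their available arrays when
    both dye levels remain and at least 3 observations exist; otherwise
    the fit is skipped (alpha/beta NaN, fitted=False).

    Returns a table (probe index preserved) with alpha, beta, se_beta,
    t_beta, beta_p, n_obs, fitted.
    """
    design = validate_design(design)
    design = design.set_index("array_id").loc[list(m_table.columns)]
    dye = design["dye"].to_numpy(float)
    M = m_table.to_numpy(float)
    n_probes = M.shape[0]

    alpha = np.full(n_probes, np.nan)
    beta = np.full(n_probes, np.nan)
    se_beta = np.full(n_probes, np.nan)
    beta_p = np.full(n_probes, np.nan)
    n_obs = np.zeros(n_probes, dtype=int)
    fitted = np.zeros(n_probes, dtype=bool)

    obs = np.isfinite(M)
    n_obs[:] = obs.sum(axis=1)
    patterns = {}
    for i in range(n_probes):
        patterns.setdefault(obs[i].tobytes(), []).append(i)

    for key, idx in patterns.items():
        mask = np.frombuffer(key, dtype=bool)
        n = int(mask.sum())
        d = dye[mask]
        if n < 3 or len(set(d)) < 2:
            continue  # skipped: single dye level or too few arrays
        X = np.column_stack([np.ones(n), d])
        XtX_inv = np.linalg.inv(X.T @ X)
        P = X @ XtX_inv  # n x 2; coef = M_sub @ P
        rows = np.asarray(idx)
        M_sub = M[np.ix_(rows, np.where(mask)[0])]
        coef = M_sub @ P
        resid = M_sub - coef @ X.T
        dof = n - 2
        sigma2 = (resid**2).sum(axis=1) / dof if dof > 0 else np.full(len(rows), np.nan)
        alpha[rows] = coef[:, 0]
        beta[rows] = coef[:, 1]
        fitted[rows] = True
        if dof > 0:
            se = np.sqrt(sigma2 * XtX_inv[1, 1])
            se_beta[rows] = se
            with np.errstate(divide="ignore", invalid="ignore"):
                tt = np.where(se > 0, coef[:, 1] / se, np.inf * np.sign(coef[:, 1]))
            tt = np.where((se == 0) & (coef[:, 1] == 0), 0.0, tt)
            beta_p[rows] = 2 * t_dist.sf(np.abs(tt), dof)

    return pd.DataFrame(
        {
            "alpha": alpha,
            "beta": beta,
            "se_beta": se_beta,
            "beta_p": beta_p,
            "n_obs": n_obs,
            "fitted": fitted,
        },
        index=m_table.index,
    )


def significant_beta_fraction(fits: pd.DataFrame, alpha_level: float = 0.05) -> float:
    """Fraction of fitted spots whose dye-bias term is significant."""
    ok = fits["fitted"] & fits["beta_p"].notna()
    if ok.sum() == 0:
        return float("nan")
    return float((fits.loc[ok, "beta_p"] < alpha_level).mean())


def correct_dye_bias(
    m_table: pd.DataFrame, fits: pd.DataFrame, design: pd.DataFrame
) -> pd.DataFrame:
    """Subtract beta * Dye_i from each oriented M value.

    Probes without a fit are passed through unchanged.
    """
    design = validate_design(design)
    design = design.set_index("array_id").loc[list(m_table.columns)]
    dye = design["dye"].to_numpy(float)
    beta = fits["beta"].to_numpy(float).copy()
    beta[~fits["fitted"].to_numpy(bool)] = 0.0
    beta = np.nan_to_num(beta)
    corrected = m_table.to_numpy(float) - np.outer(beta, dye)
    return pd.DataFrame(corrected, index=m_table.index, columns=m_table.columns)


@dataclass
class ClusterResult:
    """Ward/Euclidean dendrogram over arrays plus the two-group cut."""

    array_ids: list[str]
    linkage_matrix: np.ndarray
    labels: dict[str, int]  # two-group cut label per array

    def partition(self) -> frozenset[frozenset[str]]:
        groups: dict[int, set[str]] = {}
        for a, g in self.labels.items():
            groups.setdefault(g, set()).add(a)
        return frozenset(frozenset(g) for g in groups.values())

    def first_merges(self) -> list[frozenset[str]]:
        """Leaf pairs merged directly (both children are leaves), in merge order."""
        n = len(self.array_ids)
        pairs = []
        for a, b, _h, _c in self.linkage_matrix:
            if a < n and b < n:
                pairs.append(frozenset({self.array_ids[int(a)], self.array_ids[int(b)]}))
        return pairs

    def newick(self) -> str:
        n = len(self.array_ids)
        heights = {i: 0.0 for i in range(n)}
        nodes = {i: self.array_ids[i] for i in range(n)}
        for k, (a, b, h, _c) in enumerate(self.linkage_matrix):
            a, b = int(a), int(b)
            la = max(h - heights[a], 0.0)
            lb = max(h - heights[b], 0.0)
            nodes[n + k] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
            heights[n + k] = h
        return nodes[n + len(self.linkage_matrix) - 1] + ";"


def cluster_arrays(m_table: pd.DataFrame) -> ClusterResult:
    """Ward's minimum-variance clustering of arrays on complete-case probes."""
    if m_table.shape[1] < 2:
        raise StructuralError("need at least 2 arrays to cluster")
    complete = m_table.dropna(axis=0)
    if len(complete) < 2:
        raise StructuralError("too few complete-case probes to cluster")
    X = complete.to_numpy(float).T  # arrays x probes
    Z = linkage(X, method="ward", metric="euclidean")
    cut = fcluster(Z, t=2, criterion="maxclust")
    array_ids = list(m_table.columns)
    return ClusterResult(
        array_ids=array_ids,
        linkage_matrix=Z,
        labels=dict(zip(array_ids, (int(c) for c in cut))),
    )


def merge_samples(
    corrected: pd.DataFrame, design: pd.DataFrame, layout: ChipLayout
) -> pd.DataFrame:
    """Merge dye-swap pairs into per-sample M and average replicate probes.

    Returns a locus table (chrom, start, end, one M column per sample)
    ordered along the genome (chromosomes in layout order).  Each sample's
    M is the mean of its forward and reverse corrected values; probes
    measuring the same locus are then averaged.
    """
    design = validate_design(design)
    for sample, sub in design.groupby("sample_id"):
        if not {1, -1} <= set(sub["dye"]):
            raise StructuralError(f"sample {sample!r} lacks a dye-swap pair")
    probes = layout.probes.set_index("probe_id")
    missing = set(corrected.index) - set(probes.index)
    if missing:
        raise StructuralError(f"{len(missing)} probes absent from layout")

    per_sample = {}
    for sample, sub in design.groupby("sample_id"):
        cols = [a for a in sub["array_id"] if a in corrected.columns]
        if not cols:
            raise StructuralError(f"no arrays for sample {sample!r} in M table")
        per_sample[sample] = corrected[cols].mean(axis=1, skipna=True)
    merged = pd.DataFrame(per_sample)
    merged = merged.join(probes[["chrom", "start", "end"]])
    chrom_order = list(dict.fromkeys(layout.probes["chrom"]))
    merged["chrom"] = pd.Categorical(merged["chrom"], categories=chrom_order, ordered=True)
    out = (
        merged.groupby(["chrom", "start", "end"], sort=True, observed=True)
        .mean()
        .reset_index()
    )
    out["chrom"] = out["chrom"].astype(str)
    return out
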