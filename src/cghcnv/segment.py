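"""Circular binary segmentation (CBS) of per-sample probe M values.

Each chromosome's ordered M values are treated as a circle; the arc
(i, j] maximizing the two-sample t-like statistic (mean difference of
inside vs outside the arc, normalized by the pooled within-group SD) is
the candidate change pair.  Significance is assessed by permuting the
probe order within the tested stretch; significant arcs split the stretch
and the procedure recurses on the pieces.  Adjacent segments whose means
differ by less than ``merge_tol`` are merged afterwards (the analogue of
the "undo splits" step of reference CBS implementations), and every probe
is annotated with its segment mean — the "smoothed M" downstream CNVR
calling operates on.

The permutation loop is sequential: permutations are drawn in blocks and
stop early either when significance at ``alpha`` is already impossible
(the decision is then exact) or when, after at least 200 exceedance-free
permutations, the p-value upper bound 1/(m+1) is far below any alpha in
practical use.  Results are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cghcnv.errors import ConfigError, SegmentationError

_EARLY_SUCCESS_MIN = 200


def _max_t_rows(X: np.ndarray) -> np.ndarray:
    """Max over all arcs of |T| for each row of X (P x n).  O(P * n^2)."""
    P, n = X.shape
    S = np.concatenate([np.zeros((P, 1)), np.cumsum(X, axis=1)], axis=1)
    Q = np.concatenate([np.zeros((P, 1)), np.cumsum(X * X, axis=1)], axis=1)
    tot, qtot = S[:, -1:], Q[:, -1:]
    atol = 1e-9 * (np.abs(X).max() + 1.0)  # cancellation guard for constant data
    best = np.zeros(P)
    for k in range(1, n):
        s_in = S[:, k:] - S[:, : n - k + 1]
        q_in = Q[:, k:] - Q[:, : n - k + 1]
        m_in = s_in / k
        m_out = (tot - s_in) / (n - k)
        ssr = (q_in - k * m_in * m_in) + (qtot - q_in - (n - k) * m_out * m_out)
        denom = np.sqrt(np.maximum(ssr, 0.0) / (n - 2) * (1.0 / k + 1.0 / (n - k)))
        diff = np.abs(m_in - m_out)
        with np.errstate(divide="ignore", invalid="ignore"):
            T = diff / denom
        # zero pooled SD: infinite T when the means truly differ, else 0
        zero = denom == 0
        T[zero] = np.where(diff[zero] > atol, np.inf, 0.0)
        best = np.maximum(best, T.max(axis=1))
    return best


def max_t_statistic(values: np.ndarray) -> tuple[int, int, float]:
    """Arc (i, j] of the circularized sequence maximizing |T|.

    Returns (i, j, T) with T signed (positive when the arc mean exceeds
    the outside mean).  Only non-wrapping arcs are enumerated: a wrapping
    arc is the complement of a non-wrapping one and carries the same |T|.
    Ties are broken by smallest i, then smallest j.  A constant input has
    T = 0 for every arc and returns the tie-break arc (0, 1].
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 4:
        raise SegmentationError("need at least 4 values")
    n = len(x)
    S = np.concatenate([[0.0], np.cumsum(x)])
    Q = np.concatenate([[0.0], np.cumsum(x * x)])
    tot, qtot = S[-1], Q[-1]
    atol = 1e-9 * (np.abs(x).max() + 1.0)
    best = -1.0
    best_ij = (0, 1)
    best_sign = 1.0
    for k in range(1, n):
        s_in = S[k:] - S[: n - k + 1]
        q_in = Q[k:] - Q[: n - k + 1]
        m_in = s_in / k
        m_out = (tot - s_in) / (n - k)
        ssr = (q_in - k * m_in * m_in) + (qtot - q_in - (n - k) * m_out * m_out)
        denom = np.sqrt(np.maximum(ssr, 0.0) / (n - 2) * (1.0 / k + 1.0 / (n - k)))
        with np.errstate(divide="ignore", invalid="ignore"):
            T = (m_in - m_out) / denom
            zero = denom == 0
            d = m_in - m_out
            T[zero] = np.where(np.abs(d[zero]) > atol, np.sign(d[zero]) * np.inf, 0.0)
        absT = np.abs(T)
        i = int(absT.argmax())  # first occurrence = smallest i for this k
        if absT[i] > best:
            best = float(absT[i])
            best_ij = (i, i + k)
            best_sign = float(np.sign(T[i])) or 1.0
        elif absT[i] == best:
            cand = (i, i + k)
            if cand < best_ij:
                best_ij = cand
                best_sign = float(np.sign(T[i])) or 1.0
    return best_ij[0], best_ij[1], best_sign * best


def _split_p_value(
    x: np.ndarray,
    t_obs: float,
    alpha: float,
    nperm: int,
    rng: np.random.Generator,
    block: int = 64,
) -> float:
    """Sequential permutation p-value for the max-|T| statistic."""
    if t_obs <= 0:
        return 1.0
    exceed = 0
    done = 0
    futility = alpha * (nperm + 1) - 1  # once exceed > this, p >= alpha is certain
    while done < nperm:
        P = min(block, nperm - done)
        perm = rng.permuted(np.broadcast_to(x, (P, len(x))).copy(), axis=1)
        maxT = _max_t_rows(perm)
        exceed += int((maxT >= t_obs - 1e-12).sum())
        done += P
        if exceed > futility:
            return (exceed + 1) / (done + 1)
        if exceed == 0 and done >= min(nperm, _EARLY_SUCCESS_MIN):
            return 1.0 / (done + 1)
    return (exceed + 1) / (nperm + 1)


@dataclass
class SegmentationParams:
    alpha: float = 0.01
    nperm: int = 10_000
    merge_tol: float = 0.05  # log2 units; adjacent segments closer than this merge

    def validate(self) -> None:
        if self.nperm < 100:
            raise ConfigError("nperm must be at least 100")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.merge_tol < 0:
            raise ConfigError("merge_tol must be nonnegative")


def _recurse(
    x: np.ndarray, lo: int, hi: int, params: SegmentationParams, rng: np.random.Generator,
    bounds: list[int],
) -> None:
    n = hi - lo
    if n < 4:
        return
    i, j, T = max_t_statistic(x[lo:hi])
    if abs(T) <= 0:
        return
    p = _split_p_value(x[lo:hi], abs(T), params.alpha, params.nperm, rng)
    if p >= params.alpha:
        return
    cuts = sorted({i, j} - {0, n})
    if not cuts:
        return
    pieces = [lo] + [lo + c for c in cuts] + [hi]
    for c in pieces[1:-1]:
        bounds.append(c)
    for a, b in zip(pieces[:-1], pieces[1:]):
        _recurse(x, a, b, params, rng, bounds)


def segment_values(
    values: np.ndarray,
    params: SegmentationParams | None = None,
    seed: int = 0,
) -> list[tuple[int, int, float]]:
    """Segment one chromosome's ordered M values.

    Returns a list of (first_idx, last_idx_exclusive, seg_mean) covering
    all probes contiguously.
    """
    params = params or SegmentationParams()
    params.validate()
    x = np.asarray(values, dtype=float)
    if np.isnan(x).any():
        raise SegmentationError("missing M values must be dropped before segmentation")
    rng = np.random.default_rng(seed)
    bounds: list[int] = []
    if len(x) >= 4:
        _recurse(x, 0, len(x), params, rng, bounds)
    edges = [0] + sorted(set(bounds)) + [len(x)]
    segs = [(a, b) for a, b in zip(edges[:-1], edges[1:]) if b > a]

    # post-hoc undo: repeatedly merge the closest adjacent pair under tol
    def means(ss):
        return [float(x[a:b].mean()) for a, b in ss]

    while len(segs) > 1:
        mu = means(segs)
        diffs = [abs(mu[k + 1] - mu[k]) for k in range(len(segs) - 1)]
        k = int(np.argmin(diffs))
        if diffs[k] >= params.merge_tol:
            break
        segs[k] = (segs[k][0], segs[k + 1][1])
        del segs[k + 1]
    return [(a, b, float(x[a:b].mean())) for a, b in segs]


def segment_sample(
    m_values: pd.DataFrame,
    sample: str,
    params: SegmentationParams | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segment every chromosome of one sample's merged M values.

    ``m_values``: locus table (chrom, start, end, <sample> column) ordered
    along the genome.  Returns (segments, probes) where segments has
    columns sample_id, chrom, start, end, first_probe, n_probes, seg_mean
    and probes is m_values plus a ``smoothed`` column (the probe's segment
    mean; NaN probes are dropped).
    """
    params = params or SegmentationParams()
    if sample not in m_values.columns:
        raise SegmentationError(f"sample column {sample!r} missing")
    df = m_values.dropna(subset=[sample]).reset_index(drop=True)
    seg_rows = []
    smoothed = np.empty(len(df))
    ss = np.random.SeedSequence(seed)
    chroms = list(dict.fromkeys(df["chrom"]))
    child_seeds = {c: int(s.generate_state(1)[0] % (2**31)) for c, s in zip(chroms, ss.spawn(len(chroms)))}
    for chrom, sub in df.groupby("chrom", sort=False, observed=True):
        x = sub[sample].to_numpy(float)
        if (sub["start"].diff().dropna() < 0).any():
            raise SegmentationError(f"probes not sorted on {chrom!r}")
        if len(x) < 4:
            segs = [(0, len(x), float(np.mean(x)))] if len(x) else []
        else:
            segs = segment_values(x, params, seed=child_seeds[chrom])
        for a, b, mu in segs:
            idx = sub.index[a:b]
            smoothed[idx] = mu
            seg_rows.append(
                (
                    sample,
                    chrom,
                    int(sub["start"].iloc[a]),
                    int(sub["end"].iloc[b - 1]),
                    int(idx[0]),
                    b - a,
                    mu,
                )
            )
    probes = df.copy()
    probes["smoothed"] = smoothed
    segments = pd.DataFrame(
        seg_rows,
        columns=["sample_id", "chrom", "start", "end", "first_probe", "n_probes", "seg_mean"],
    )
    return segments, probes
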