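"""Chip layout tiling and two-color dye-swap hybridization simulation.

The simulator emulates a tiling CGH platform: probes laid along the
chromosomes at a target median spacing and mapped row-major onto the chip
grid, then per-spot two-channel intensities for a dye-swap design (each
test individual hybridized once "forward", test labeled red, and once
"reverse", dyes exchanged, against a pooled reference).

Signal model, on the log2 scale, for a spot measuring a probe with planted
copy state ``c`` in sample ``s``::

    M_raw = direction * (log2(c/2) + eps) + bias + gradient(row, col)

with ``direction`` +1 on forward and -1 on reverse chips, ``eps`` the
measurement noise attached to the biological quantity, ``bias`` the
spot-specific dye bias (a chip-orientation-independent property of the
spot), and ``gradient`` a smooth spatial artifact of the individual chip.
After orientation adjustment (reverse M multiplied by -1) the dye bias
therefore enters with sign +1 on forward and -1 on reverse chips, which is
exactly the two-regressor linear model the correction stage fits.

Raw intensities are reconstructed from M and a per-spot average log2
intensity A as ``net = 2**(A ± M/2)`` plus an additive background, so
foreground-minus-background subtraction downstream recovers M exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cghcnv.errors import ConfigError, StructuralError
from cghcnv.genome import GenomeModel, TruthSet

SCAN_COLUMNS = [
    "probe_id",
    "grid_row",
    "grid_col",
    "ch_red_fg",
    "ch_red_bg",
    "ch_green_fg",
    "ch_green_bg",
    "qc_flag",
]


@dataclass
class ChipLayout:
    """Probe table with genomic coordinates and chip grid positions."""

    probes: pd.DataFrame  # probe_id, chrom, start, end, grid_row, grid_col
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        required = {"probe_id", "chrom", "start", "end", "grid_row", "grid_col"}
        missing = required - set(self.probes.columns)
        if missing:
            raise StructuralError(f"layout missing columns {missing}")
        grid = self.probes[["grid_row", "grid_col"]]
        if grid.duplicated().any():
            raise StructuralError("duplicate grid positions in layout")

    def __len__(self) -> int:
        return len(self.probes)

    def replicate_groups(self) -> pd.core.groupby.DataFrameGroupBy:
        """Group probes measuring the same locus."""
        return self.probes.groupby(["chrom", "start", "end"], sort=False)

    def write(self, path) -> None:
        self.probes.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "ChipLayout":
        probes = pd.read_csv(path, sep="\t")
        return cls(
            probes=probes,
            n_rows=int(probes["grid_row"].max()) + 1,
            n_cols=int(probes["grid_col"].max()) + 1,
        )


@dataclass
class ArrayScan:
    """One hybridization: per-spot two-channel intensities plus metadata."""

    array_id: str
    sample_id: str
    orientation: str  # "forward" | "reverse"
    spots: pd.DataFrame  # SCAN_COLUMNS

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise ConfigError(f"unknown orientation {self.orientation!r}")
        missing = set(SCAN_COLUMNS) - set(self.spots.columns)
        if missing:
            raise StructuralError(f"scan missing columns {missing}")
        for col in ("ch_red_fg", "ch_red_bg", "ch_green_fg", "ch_green_bg"):
            if (self.spots[col] < 0).any():
                raise StructuralError(f"negative intensities in {col}")

    @property
    def direction(self) -> int:
        return 1 if self.orientation == "forward" else -1

    def write(self, path) -> None:
        header = f"# array_id={self.array_id}\tsample_id={self.sample_id}\torientation={self.orientation}\n"
        with open(path, "w") as fh:
            fh.write(header)
            self.spots.to_csv(fh, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def read(cls, path) -> "ArrayScan":
        with open(path) as fh:
            meta = dict(
                item.split("=", 1) for item in fh.readline().lstrip("# ").strip().split("\t")
            )
            spots = pd.read_csv(fh, sep="\t")
        return cls(
            array_id=meta["array_id"],
            sample_id=meta["sample_id"],
            orientation=meta["orientation"],
            spots=spots,
        )


@dataclass
class DyeBiasSpec:
    """Spot-specific dye bias: zero-mean normal background plus a fraction
    of spots carrying a large fixed offset (random sign)."""

    sd: float = 0.05
    big_fraction: float = 0.25
    big_magnitude: float = 0.4

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        bias = rng.normal(0.0, self.sd, n) if self.sd > 0 else np.zeros(n)
        if self.big_fraction > 0:
            hit = rng.random(n) < self.big_fraction
            sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
            bias = bias + hit * sign * self.big_magnitude
        return bias


@dataclass
class GradientSpec:
    """Smooth low-order polynomial over normalized grid coordinates."""

    amplitude: float = 0.0  # max |contribution| of each term, log2 units

    def draw(
        self, n_rows: int, n_cols: int, rng: np.random.Generator
    ) -> np.ndarray:
        # coefficient draws consumed even when amplitude == 0 so that
        # turning the gradient on/off does not shift downstream streams
        coef = rng.uniform(-1.0, 1.0, 4) * self.amplitude
        u = (np.arange(n_rows) / max(n_rows - 1, 1) - 0.5) * 2
        v = (np.arange(n_cols) / max(n_cols - 1, 1) - 0.5) * 2
        U, V = np.meshgrid(u, v, indexing="ij")
        return coef[0] * U + coef[1] * V + coef[2] * U * V + coef[3] * (U**2 + V**2) / 2


@dataclass
class BadBlockSpec:
    """Rectangular low-quality chip region with inflated variance."""

    row0: int
    row1: int
    col0: int
    col1: int
    extra_sd: float = 1.0

    def mask(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return (
            (rows >= self.row0)
            & (rows < self.row1)
            & (cols >= self.col0)
            & (cols < self.col1)
        )


def tile_probes(
    genome: GenomeModel,
    target_spacing: int = 7_900,
    probe_length: int = 60,
    jitter_frac: float = 0.1,
    replicate_fraction: float = 0.01,
    seed: int = 0,
) -> ChipLayout:
    """Tile probes along every chromosome at the target median spacing.

    Inter-probe steps are the target spacing perturbed by a uniform
    +/- ``jitter_frac`` jitter, so the median spacing stays on target. A
    small fraction of loci receive a duplicate spot (replicate probes), as
    on real tiling chips.  Grid positions are assigned row-major in probe
    order on a near-square grid.
    """
    if target_spacing <= probe_length:
        raise ConfigError("target_spacing must exceed probe_length")
    rng = np.random.default_rng(seed)
    rows = []
    idx = 0
    for chrom, length in genome.chromosomes.items():
        if length < probe_length:
            continue
        pos = int(min(target_spacing // 2, length - probe_length))
        while True:
            rows.append((f"p{idx:06d}", chrom, pos, pos + probe_length))
            idx += 1
            step = int(round(target_spacing * (1 + rng.uniform(-jitter_frac, jitter_frac))))
            pos = pos + max(step, probe_length + 1)
            if pos + probe_length > length:
                break
    probes = pd.DataFrame(rows, columns=["probe_id", "chrom", "start", "end"])
    if replicate_fraction > 0 and len(probes) > 0:
        dup = probes[rng.random(len(probes)) < replicate_fraction].copy()
        dup["probe_id"] = "r" + dup["probe_id"].str.lstrip("p")
        probes = pd.concat([probes, dup], ignore_index=True)
    n = len(probes)
    n_cols = max(int(math.ceil(math.sqrt(n))), 1)
    n_rows = int(math.ceil(n / n_cols))
    probes["grid_row"] = np.arange(n) // n_cols
    probes["grid_col"] = np.arange(n) % n_cols
    return ChipLayout(probes=probes, n_rows=n_rows, n_cols=n_cols)


def expected_m(layout: ChipLayout, truth: TruthSet, sample_id: str) -> np.ndarray:
    """Noise-free biological M per probe: log2(copy/2) of the planted state."""
    m = np.zeros(len(layout))
    sub = truth.for_sample(sample_id)
    starts = layout.probes["start"].values
    ends = layout.probes["end"].values
    chroms = layout.probes["chrom"].values
    for row in sub.itertuples():
        inside = (chroms == row.chrom) & (starts < row.end) & (ends > row.start)
        m[inside] = np.log2(row.copy_state / 2.0)
    return m


def make_dye_bias(
    layout: ChipLayout, spec: DyeBiasSpec | None = None, seed: int = 0
) -> np.ndarray:
    """Per-spot dye bias.  A property of the spot, shared by all chips."""
    spec = spec or DyeBiasSpec()
    return spec.draw(len(layout), np.random.default_rng(seed))


def simulate_hybridization(
    layout: ChipLayout,
    truth: TruthSet,
    sample_id: str,
    orientation: str,
    bias: np.ndarray | None = None,
    gradient: GradientSpec | None = None,
    noise_sd: float = 0.15,
    bad_block: BadBlockSpec | None = None,
    dropout_fraction: float = 0.0,
    a_mean: float = 10.0,
    a_sd: float = 1.0,
    bg_log2_mean: float = 6.0,
    array_id: str | None = None,
    seed: int = 0,
    noise_seed: int | None = None,
) -> ArrayScan:
    """Simulate one hybridization of ``sample_id`` in the given orientation.

    ``bias`` is the per-spot dye-bias vector (see :func:`make_dye_bias`);
    ``noise_seed`` lets a forward/reverse pair share measurement noise so
    the 2x-bias identity can be checked exactly.  Deterministic for fixed
    seeds.
    """
    if noise_sd < 0:
        raise ConfigError("noise_sd must be nonnegative")
    if orientation not in ("forward", "reverse"):
        raise ConfigError(f"unknown orientation {orientation!r}")
    if truth.cnvs.shape[0] and sample_id not in truth.sample_ids:
        raise LookupError(f"unknown sample_id {sample_id!r}")
    n = len(layout)
    rng = np.random.default_rng(seed)
    noise_rng = np.random.default_rng(noise_seed) if noise_seed is not None else rng
    direction = 1 if orientation == "forward" else -1

    m_bio = expected_m(layout, truth, sample_id)
    eps = noise_rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
    rows = layout.probes["grid_row"].values
    cols = layout.probes["grid_col"].values
    grad = (gradient or GradientSpec()).draw(layout.n_rows, layout.n_cols, rng)[rows, cols]
    bias = np.zeros(n) if bias is None else np.asarray(bias, dtype=float)
    if bias.shape != (n,):
        raise StructuralError("bias vector length does not match layout")

    m_raw = direction * (m_bio + eps) + bias + grad
    if bad_block is not None:
        blk = bad_block.mask(rows, cols)
        m_raw = m_raw + blk * rng.normal(0.0, bad_block.extra_sd, n)

    a = rng.normal(a_mean, a_sd, n)
    net_red = np.exp2(a + m_raw / 2.0)
    net_green = np.exp2(a - m_raw / 2.0)
    bg = np.exp2(rng.normal(bg_log2_mean, 0.3, n))
    red_fg = net_red + bg
    green_fg = net_green + bg
    if dropout_fraction > 0:
        dead = rng.random(n) < dropout_fraction
        red_fg = np.where(dead, bg * rng.uniform(0.2, 1.0, n), red_fg)
        green_fg = np.where(dead, bg * rng.uniform(0.2, 1.0, n), green_fg)

    spots = pd.DataFrame(
        {
            "probe_id": layout.probes["probe_id"].values,
            "grid_row": rows,
            "grid_col": cols,
            "ch_red_fg": red_fg,
            "ch_red_bg": bg,
            "ch_green_fg": green_fg,
            "ch_green_bg": bg,
            "qc_flag": "pass",
        }
    )
    if array_id is None:
        array_id = f"{sample_id}_{'F' if direction == 1 else 'R'}"
    return ArrayScan(
        array_id=array_id, sample_id=sample_id, orientation=orientation, spots=spots
    )


@dataclass
class SimulatedStudy:
    """A full dye-swap study: genome, truth, layout, bias, and 6 scans."""

    genome: GenomeModel
    truth: TruthSet
    layout: ChipLayout
    bias: np.ndarray
    scans: list[ArrayScan] = field(default_factory=list)

    def design(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "array_id": [s.array_id for s in self.scans],
                "sample_id": [s.sample_id for s in self.scans],
                "orientation": [s.orientation for s in self.scans],
            }
        )


def simulate_study(
    genome: GenomeModel,
    truth: TruthSet,
    layout: ChipLayout,
    bias_spec: DyeBiasSpec | None = None,
    gradient: GradientSpec | None = None,
    noise_sd: float = 0.15,
    bad_block: BadBlockSpec | None = None,
    dropout_fraction: float = 0.0,
    seed: int = 0,
) -> SimulatedStudy:
    """Simulate the full forward+reverse design over all truth samples.

    One sub-seed per array is derived from the master seed via a
    splittable seed sequence, so any array is reproducible in isolation.
    """
    ss = np.random.SeedSequence(seed)
    bias_seed, *array_seeds = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(1 + 2 * len(truth.sample_ids))
    ]
    bias = make_dye_bias(layout, bias_spec, seed=bias_seed)
    scans = []
    k = 0
    for sample_id in truth.sample_ids:
        for orientation in ("forward", "reverse"):
            scans.append(
                simulate_hybridization(
                    layout,
                    truth,
                    sample_id,
                    orientation,
                    bias=bias,
                    gradient=gradient,
                    noise_sd=noise_sd,
                    bad_block=bad_block if k == 2 * len(truth.sample_ids) - 1 else None,
                    dropout_fraction=dropout_fraction,
                    seed=array_seeds[k],
                )
            )
            k += 1
    return SimulatedStudy(genome=genome, truth=truth, layout=layout, bias=bias, scans=scans)
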