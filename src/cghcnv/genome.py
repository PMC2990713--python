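"""Synthetic diploid genome with annotated feature interval sets.

The genome model plays the role a reference assembly plus its annotation
tables play for real arrays: ordered chromosomes with lengths, and named
interval sets (genes, ultraconserved elements, miRNAs, QTLs).  Coordinates
are 0-based, half-open throughout, as in BED.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cghcnv.errors import ConfigError, PlacementError, StructuralError

FEATURE_COLUMNS = ["chrom", "start", "end", "id", "strand"]


@dataclass
class GenomeModel:
    """Chromosome lengths plus named feature interval sets.

    chromosomes: ordered mapping name -> length (bp).
    features: mapping set name -> DataFrame with columns
        chrom, start, end, id, strand.
    """

    chromosomes: dict[str, int]
    features: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.chromosomes:
            raise ConfigError("genome needs at least one chromosome")
        for name, length in self.chromosomes.items():
            if length <= 0:
                raise ConfigError(f"chromosome {name!r} has nonpositive length")
        for set_name, df in self.features.items():
            missing = set(FEATURE_COLUMNS) - set(df.columns)
            if missing:
                raise StructuralError(f"feature set {set_name!r} missing columns {missing}")
            if len(df) == 0:
                continue
            if df["id"].duplicated().any():
                raise StructuralError(f"duplicate feature ids in set {set_name!r}")
            for chrom, sub in df.groupby("chrom", sort=False):
                if chrom not in self.chromosomes:
                    raise StructuralError(f"feature on unknown chromosome {chrom!r}")
                L = self.chromosomes[chrom]
                if (sub["start"] < 0).any() or (sub["end"] > L).any() or (
                    sub["start"] >= sub["end"]
                ).any():
                    raise StructuralError(
                        f"feature interval out of bounds on {chrom!r} in {set_name!r}"
                    )

    @property
    def total_length(self) -> int:
        return int(sum(self.chromosomes.values()))

    def chrom_order(self) -> list[str]:
        return list(self.chromosomes)

    # ------------------------------------------------------------------ I/O

    def write(self, outdir: str | Path) -> list[Path]:
        """Write chrom.sizes plus one BED file per feature set."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        sizes = outdir / "chrom.sizes"
        with open(sizes, "w") as fh:
            for name, length in self.chromosomes.items():
                fh.write(f"{name}\t{length}\n")
        written.append(sizes)
        for set_name, df in self.features.items():
            path = outdir / f"{set_name}.bed"
            bed = df[["chrom", "start", "end", "id"]].copy()
            bed["score"] = 0
            bed["strand"] = df["strand"]
            bed.to_csv(path, sep="\t", header=False, index=False)
            written.append(path)
        return written

    @classmethod
    def read(cls, indir: str | Path, feature_sets: list[str] | None = None) -> "GenomeModel":
        indir = Path(indir)
        chroms: dict[str, int] = {}
        with open(indir / "chrom.sizes") as fh:
            for line in fh:
                name, length = line.split()
                chroms[name] = int(length)
        if feature_sets is None:
            feature_sets = [p.stem for p in sorted(indir.glob("*.bed"))]
        features = {}
        for set_name in feature_sets:
            df = pd.read_csv(
                indir / f"{set_name}.bed",
                sep="\t",
                header=None,
                names=["chrom", "start", "end", "id", "score", "strand"],
            )
            features[set_name] = df[FEATURE_COLUMNS].copy()
        return cls(chromosomes=chroms, features=features)


@dataclass
class TruthSet:
    """Planted CNVs: ground truth for parameter-recovery checks.

    cnvs: DataFrame with columns sample_id, chrom, start, end, copy_state
    (1 = one-copy loss, 3 = one-copy gain; diploid baseline 2 elsewhere)
    and cnv_id (shared CNVs carry the same id in every sample).
    """

    cnvs: pd.DataFrame

    COLUMNS = ["sample_id", "chrom", "start", "end", "copy_state", "cnv_id"]

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.cnvs.columns)
        if missing:
            raise StructuralError(f"truth set missing columns {missing}")
        bad_state = ~self.cnvs["copy_state"].isin([1, 3])
        if bad_state.any():
            raise StructuralError("copy_state must be 1 or 3")
        for (sample, chrom), sub in self.cnvs.groupby(["sample_id", "chrom"], sort=False):
            s = sub.sort_values("start")
            if (s["end"].values[:-1] > s["start"].values[1:]).any():
                raise StructuralError(
                    f"overlapping planted CNVs for sample {sample!r} on {chrom!r}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.cnvs["sample_id"].unique())

    def for_sample(self, sample_id: str) -> pd.DataFrame:
        return self.cnvs[self.cnvs["sample_id"] == sample_id]

    def n_shared(self) -> int:
        """Number of CNV ids present in every sample."""
        samples = self.sample_ids
        if not samples:
            return 0
        counts = self.cnvs.groupby("cnv_id")["sample_id"].nunique()
        return int((counts == len(samples)).sum())

    def write(self, path: str | Path) -> None:
        self.cnvs.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "TruthSet":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class GenomeConfig:
    """Parameters of the synthetic genome.

    Defaults are a ~100 Mb, 16-chromosome scale model of a mammalian
    genome with a merged gene fraction of 21% (the whole-genome gene
    fraction the analysis compares CNVR gene content against).
    """

    n_chromosomes: int = 16
    chrom_length: int = 6_250_000
    gene_fraction: float = 0.21
    gene_length_log2_mean: float = 14.0  # median gene ~16 Kb
    gene_length_log2_sd: float = 0.8
    n_ultraconserved: int = 100
    ultraconserved_length: tuple[int, int] = (200, 780)
    n_mirnas: int = 60
    mirna_length: tuple[int, int] = (70, 120)
    n_qtls: int = 10
    qtl_length: tuple[int, int] = (1_000_000, 3_000_000)

    def validate(self) -> None:
        if self.n_chromosomes < 1:
            raise ConfigError("need at least one chromosome")
        if self.chrom_length <= 0:
            raise ConfigError("chromosome length must be positive")
        if not 0.0 <= self.gene_fraction <= 1.0:
            raise ConfigError("gene_fraction must be in [0, 1]")
        for name in ("n_ultraconserved", "n_mirnas", "n_qtls"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")


def _place_nonoverlapping(
    length: int, sizes: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Place intervals of the given sizes in [0, length) without overlap.

    Free space is distributed as random gaps between the intervals
    (stick-breaking), so total coverage equals sum(sizes) exactly.
    """
    total = int(sizes.sum())
    if total > length:
        raise PlacementError("intervals do not fit on chromosome")
    free = length - total
    cuts = np.sort(rng.integers(0, free + 1, size=len(sizes)))
    order = rng.permutation(len(sizes))
    starts = cuts + np.concatenate([[0], np.cumsum(sizes[order])[:-1]])
    out = np.empty(len(sizes), dtype=np.int64)
    out[order] = starts
    return out


def make_genome(config: GenomeConfig | None = None, seed: int = 0) -> GenomeModel:
    """Generate a deterministic synthetic genome with feature annotations.

    Gene intervals are placed without overlap so the merged gene coverage
    matches ``config.gene_fraction`` up to the rounding of the last gene
    length on each chromosome.  Other feature sets (ultraconserved
    elements, miRNAs, QTLs) are placed uniformly and may overlap genes,
    as they do in real annotations.
    """
    config = config or GenomeConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    chroms = {
        f"chr{i + 1}": int(config.chrom_length) for i in range(config.n_chromosomes)
    }
    genes = []
    for chrom, length in chroms.items():
        target = int(round(config.gene_fraction * length))
        sizes: list[int] = []
        while sum(sizes) < target:
            size = int(
                round(2 ** rng.normal(config.gene_length_log2_mean, config.gene_length_log2_sd))
            )
            size = max(size, 200)
            sizes.append(size)
        if sizes:
            sizes[-1] -= sum(sizes) - target  # trim last gene to hit the target
            if sizes[-1] < 200:
                sizes.pop()
        if not sizes:
            continue
        arr = np.asarray(sizes, dtype=np.int64)
        starts = _place_nonoverlapping(length, arr, rng)
        for s, size in zip(starts, arr):
            genes.append((chrom, int(s), int(s + size)))
    gene_df = pd.DataFrame(genes, columns=["chrom", "start", "end"])
    gene_df["id"] = [f"gene{i:05d}" for i in range(len(gene_df))]
    gene_df["strand"] = np.where(rng.random(len(gene_df)) < 0.5, "+", "-")

    def uniform_features(n: int, size_range: tuple[int, int], prefix: str) -> pd.DataFrame:
        rows = []
        names = list(chroms)
        lengths = np.array([chroms[c] for c in names], dtype=float)
        probs = lengths / lengths.sum()
        for i in range(n):
            chrom = names[rng.choice(len(names), p=probs)]
            size = int(rng.integers(size_range[0], size_range[1] + 1))
            size = min(size, chroms[chrom])
            start = int(rng.integers(0, chroms[chrom] - size + 1))
            rows.append((chrom, start, start + size, f"{prefix}{i:04d}", "."))
        return pd.DataFrame(rows, columns=FEATURE_COLUMNS)

    features = {
        "genes": gene_df[FEATURE_COLUMNS],
        "ucsc_elements": uniform_features(
            config.n_ultraconserved, config.ultraconserved_length, "uc"
        ),
        "mirnas": uniform_features(config.n_mirnas, config.mirna_length, "mir"),
        "qtls": uniform_features(config.n_qtls, config.qtl_length, "qtl"),
    }
    return GenomeModel(chromosomes=chroms, features=features)


def plant_cnvs(
    genome: GenomeModel,
    n_per_sample: int,
    length_range: tuple[int, int] = (50_000, 500_000),
    shared_fraction: float = 0.7,
    sample_ids: list[str] | None = None,
    min_separation: int = 50_000,
    seed: int = 0,
    max_tries: int = 10_000,
) -> TruthSet:
    """Plant gain (copy 3) and loss (copy 1) CNVs for each sample.

    ``round(shared_fraction * n_per_sample)`` CNVs are identical across all
    samples (emulating the cross-individual consistency of real CNVs); the
    remainder are private to each sample.  Within one sample CNVs never
    overlap and keep ``min_separation`` bp apart so planted regions stay
    distinct after flank extension.  Gains and losses alternate, so both
    states are always represented when n_per_sample >= 2.
    """
    if n_per_sample < 0:
        raise ConfigError("n_per_sample must be nonnegative")
    if not 0.0 <= shared_fraction <= 1.0:
        raise ConfigError("shared_fraction must be in [0, 1]")
    if length_range[0] > length_range[1] or length_range[0] <= 0:
        raise ConfigError("invalid CNV length range")
    sample_ids = sample_ids or ["GK1", "GK2", "GK3"]
    rng = np.random.default_rng(seed)
    columns = TruthSet.COLUMNS
    if n_per_sample == 0:
        return TruthSet(pd.DataFrame(columns=columns))

    names = genome.chrom_order()
    lengths = np.array([genome.chromosomes[c] for c in names], dtype=float)
    occupied: dict[str, list[tuple[str, int, int]]] = {s: [] for s in sample_ids}

    def try_place(samples: list[str]) -> tuple[str, int, int] | None:
        size = int(rng.integers(length_range[0], length_range[1] + 1))
        valid = np.maximum(lengths - size + 1, 0)
        if valid.sum() == 0:
            return None
        probs = valid / valid.sum()
        chrom = names[rng.choice(len(names), p=probs)]
        start = int(rng.integers(0, genome.chromosomes[chrom] - size + 1))
        end = start + size
        for s in samples:
            for oc, os, oe in occupied[s]:
                if oc == chrom and start - min_separation < oe and os < end + min_separation:
                    return None
        return chrom, start, end

    n_shared = int(round(shared_fraction * n_per_sample))
    rows = []
    counter = 0

    def place(samples: list[str]) -> tuple[str, int, int]:
        for _ in range(max_tries):
            hit = try_place(samples)
            if hit is not None:
                return hit
        raise PlacementError("could not place CNV without overlap; genome too crowded")

    for k in range(n_shared):
        state = 3 if k % 2 == 0 else 1
        chrom, start, end = place(sample_ids)
        cnv_id = f"cnv{counter:04d}"
        counter += 1
        for s in sample_ids:
            occupied[s].append((chrom, start, end))
            rows.append((s, chrom, start, end, state, cnv_id))
    for s in sample_ids:
        for k in range(n_per_sample - n_shared):
            state = 3 if k % 2 == 1 else 1  # offset so privates also alternate
            chrom, start, end = place([s])
            cnv_id = f"cnv{counter:04d}"
            counter += 1
            occupied[s].append((chrom, start, end))
            rows.append((s, chrom, start, end, state, cnv_id))
    df = pd.DataFrame(rows, columns=columns)
    df = df.sort_values(["sample_id", "chrom", "start"]).reset_index(drop=True)
    return TruthSet(df)
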