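"""End-to-end orchestration: simulate -> preprocess -> correct -> segment
-> call -> annotate -> permtest -> enrich (-> de), with every intermediate
persisted in standard text formats and a JSON run manifest.

Each stage is a function over a workspace directory, so the CLI can rerun
any stage with the manifest's parameters and reproduce ``run_all`` output
byte for byte (all randomness flows from the global seed through named
sub-seeds; all floats are written with fixed formats).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from cghcnv import cnvr as cnvr_mod
from cghcnv import dyeswap, enrich, expression, intervals, preprocess, segment
from cghcnv.errors import ConfigError
from cghcnv.genome import GenomeConfig, GenomeModel, TruthSet, make_genome, plant_cnvs
from cghcnv.simulate import (
    ArrayScan,
    BadBlockSpec,
    ChipLayout,
    DyeBiasSpec,
    GradientSpec,
    simulate_study,
    tile_probes,
)

log = logging.getLogger("cghcnv")

FLOAT_FMT = "%.6f"


@dataclass
class SimulateConfig:
    enabled: bool = True
    n_chromosomes: int = 16
    chrom_length: int = 6_250_000
    gene_fraction: float = 0.21
    n_samples: int = 3
    cnvs_per_sample: int = 40
    cnv_length_min: int = 50_000
    cnv_length_max: int = 500_000
    shared_fraction: float = 0.7
    probe_spacing: int = 7_900
    noise_sd: float = 0.15
    bias_sd: float = 0.05
    bias_big_fraction: float = 0.25
    bias_big_magnitude: float = 0.4
    gradient_amplitude: float = 0.05
    dropout_fraction: float = 0.002
    bad_block: bool = True


@dataclass
class PreprocessConfig:
    span: float = 0.3
    qc_window: int = 10
    qc_outlier_mad: float = 3.0
    qc_window_flag_frac: float = 0.4


@dataclass
class CorrectConfig:
    alpha_level: float = 0.05


@dataclass
class SegmentConfig:
    alpha: float = 0.01
    nperm: int = 2_000
    merge_tol: float = 0.05


@dataclass
class CallConfig:
    threshold: float = 0.5
    min_probes: int = 3
    flank: int = 5_000
    max_gap: int = 0  # 0 means no maximum-gap rule


@dataclass
class PermtestConfig:
    n_rounds: int = 1_000


@dataclass
class EnrichConfig:
    enabled: bool = True
    n_random_sets: int = 20
    set_size_min: int = 20
    set_size_max: int = 80
    spike_fraction: float = 0.5  # of the spiked set drawn from CNV genes


@dataclass
class DEConfig:
    enabled: bool = False
    n_test: int = 4
    n_control: int = 4
    fdr_threshold: float = 0.2
    effect_log2: float = 1.0
    noise_sd: float = 0.25
    consistent_fraction: float = 0.7


@dataclass
class PipelineConfig:
    seed: int = 0
    log_level: str = "INFO"
    genome_dir: str | None = None  # required when simulate.enabled is False
    scans_dir: str | None = None
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    correct: CorrectConfig = field(default_factory=CorrectConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    call: CallConfig = field(default_factory=CallConfig)
    permtest: PermtestConfig = field(default_factory=PermtestConfig)
    enrich: EnrichConfig = field(default_factory=EnrichConfig)
    de: DEConfig = field(default_factory=DEConfig)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        sections = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for key, value in raw.items():
            if key not in sections:
                raise ConfigError(f"unknown config key {key!r}")
            ftype = sections[key].default_factory if sections[key].default_factory is not dataclasses.MISSING else None
            if ftype is not None and isinstance(value, dict):
                sub_cls = ftype().__class__
                known = {f.name for f in dataclasses.fields(sub_cls)}
                unknown = set(value) - known
                if unknown:
                    raise ConfigError(f"unknown keys {unknown} in section {key!r}")
                kwargs[key] = sub_cls(**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def validate(self) -> None:
        if not self.simulate.enabled:
            if not self.genome_dir or not Path(self.genome_dir).exists():
                raise ConfigError("genome_dir required (and must exist) without simulation")
            if not self.scans_dir or not Path(self.scans_dir).exists():
                raise ConfigError("scans_dir required (and must exist) without simulation")


def _subseed(seed: int, label: str) -> int:
    h = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class RunManifest:
    def __init__(self, seed: int):
        self.data = {"seed": seed, "stages": {}}

    def record(self, stage: str, params: dict, outputs: list[Path], t0: float,
               inputs: list[Path] | None = None) -> None:
        self.data["stages"][stage] = {
            "params": params,
            "inputs": {str(p): _sha256(Path(p)) for p in (inputs or [])},
            "outputs": [str(p) for p in outputs],
            "elapsed_s": round(time.time() - t0, 2),
        }

    def write(self, path: Path) -> None:
        tmp = path.with_suffix(".tmp")
        tmp.write_text(json.dumps(self.data, indent=2) + "\n")
        tmp.replace(path)


# --------------------------------------------------------------- stages


def stage_simulate(config: PipelineConfig, outdir: Path) -> list[Path]:
    sim = config.simulate
    gcfg = GenomeConfig(
        n_chromosomes=sim.n_chromosomes,
        chrom_length=sim.chrom_length,
        gene_fraction=sim.gene_fraction,
    )
    genome = make_genome(gcfg, seed=_subseed(config.seed, "genome"))
    truth = plant_cnvs(
        genome,
        n_per_sample=sim.cnvs_per_sample,
        length_range=(sim.cnv_length_min, sim.cnv_length_max),
        shared_fraction=sim.shared_fraction,
        sample_ids=[f"GK{i + 1}" for i in range(sim.n_samples)],
        seed=_subseed(config.seed, "truth"),
    )
    layout = tile_probes(
        genome, target_spacing=sim.probe_spacing, seed=_subseed(config.seed, "layout")
    )
    n_rows = layout.n_rows
    block = (
        BadBlockSpec(
            row0=(n_rows // 4) * 2, row1=(n_rows // 4) * 2 + 20,
            col0=20, col1=40, extra_sd=1.0,
        )
        if sim.bad_block
        else None
    )
    study = simulate_study(
        genome,
        truth,
        layout,
        bias_spec=DyeBiasSpec(sim.bias_sd, sim.bias_big_fraction, sim.bias_big_magnitude),
        gradient=GradientSpec(sim.gradient_amplitude),
        noise_sd=sim.noise_sd,
        bad_block=block,
        dropout_fraction=sim.dropout_fraction,
        seed=_subseed(config.seed, "study"),
    )
    outputs = []
    outputs += genome.write(outdir / "genome")
    truth.write(outdir / "truth.tsv")
    layout.write(outdir / "layout.tsv")
    scans_dir = outdir / "scans"
    scans_dir.mkdir(exist_ok=True)
    for scan in study.scans:
        scan.write(scans_dir / f"{scan.array_id}.tsv")
        outputs.append(scans_dir / f"{scan.array_id}.tsv")
    design = study.design()
    design.to_csv(outdir / "design.tsv", sep="\t", index=False)
    outputs += [outdir / "truth.tsv", outdir / "layout.tsv", outdir / "design.tsv"]
    log.info(
        "simulate: %d chrom / %d probes / %d planted CNVs per sample",
        sim.n_chromosomes, len(layout), sim.cnvs_per_sample,
    )
    return outputs


def stage_preprocess(config: PipelineConfig, outdir: Path) -> list[Path]:
    design = pd.read_csv(outdir / "design.tsv", sep="\t")
    qc = preprocess.QCParams(
        window=config.preprocess.qc_window,
        outlier_mad=config.preprocess.qc_outlier_mad,
        window_flag_frac=config.preprocess.qc_window_flag_frac,
    )
    pre_dir = outdir / "preprocessed"
    pre_dir.mkdir(exist_ok=True)
    outputs = []
    scans_dir = Path(config.scans_dir) if config.scans_dir else outdir / "scans"
    for array_id in design["array_id"]:
        scan = ArrayScan.read(scans_dir / f"{array_id}.tsv")
        spots = preprocess.preprocess_scan(scan, qc_params=qc, span=config.preprocess.span)
        n_fail = int((spots["qc"] == "fail").sum())
        log.info("preprocess %s: %d spots flagged", array_id, n_fail)
        path = pre_dir / f"{array_id}.tsv"
        spots.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
        outputs.append(path)
    return outputs


def stage_correct(config: PipelineConfig, outdir: Path) -> list[Path]:
    design = pd.read_csv(outdir / "design.tsv", sep="\t")
    layout = ChipLayout.read(outdir / "layout.tsv")
    m_cols = {}
    for array_id in design["array_id"]:
        t = pd.read_csv(outdir / "preprocessed" / f"{array_id}.tsv", sep="\t")
        m_cols[array_id] = t.set_index("probe_id")["M"]
    m_table = pd.DataFrame(m_cols)

    before = dyeswap.cluster_arrays(m_table)
    fits = dyeswap.fit_dye_model(m_table, design)
    frac = dyeswap.significant_beta_fraction(fits, config.correct.alpha_level)
    log.info("correct: %.1f%% of spots with significant dye bias (p<%g)",
             100 * frac, config.correct.alpha_level)
    corrected = dyeswap.correct_dye_bias(m_table, fits, design)
    after = dyeswap.cluster_arrays(corrected)
    merged = dyeswap.merge_samples(corrected, design, layout)

    outputs = []
    for name, obj in (
        ("fits.tsv", fits.rename_axis("probe_id").reset_index()),
        ("corrected.tsv", corrected.rename_axis("probe_id").reset_index()),
        ("merged_m.tsv", merged),
    ):
        path = outdir / name
        obj.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
        outputs.append(path)
    for name, cl in (("cluster_before.nwk", before), ("cluster_after.nwk", after)):
        path = outdir / name
        path.write_text(cl.newick() + "\n")
        outputs.append(path)
    (outdir / "dye_bias_fraction.json").write_text(
        json.dumps({"significant_beta_fraction": frac, "alpha": config.correct.alpha_level})
        + "\n"
    )
    outputs.append(outdir / "dye_bias_fraction.json")
    return outputs


def _sample_columns(merged: pd.DataFrame) -> list[str]:
    return [c for c in merged.columns if c not in ("chrom", "start", "end")]


def stage_segment(config: PipelineConfig, outdir: Path) -> list[Path]:
    merged = pd.read_csv(outdir / "merged_m.tsv", sep="\t")
    params = segment.SegmentationParams(
        alpha=config.segment.alpha,
        nperm=config.segment.nperm,
        merge_tol=config.segment.merge_tol,
    )
    outputs = []
    seg_frames = []
    for sample in _sample_columns(merged):
        segs, probes = segment.segment_sample(
            merged, sample, params, seed=_subseed(config.seed, f"segment:{sample}")
        )
        seg_frames.append(segs)
        path = outdir / f"smoothed_{sample}.tsv"
        probes.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
        outputs.append(path)
        log.info("segment %s: %d segments", sample, len(segs))
    path = outdir / "segments.tsv"
    pd.concat(seg_frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT
    )
    outputs.append(path)
    return outputs


def stage_call(config: PipelineConfig, outdir: Path) -> list[Path]:
    genome = GenomeModel.read(outdir / "genome")
    merged = pd.read_csv(outdir / "merged_m.tsv", sep="\t")
    cc = config.call
    per_sample = []
    outputs = []
    for sample in _sample_columns(merged):
        probes = pd.read_csv(outdir / f"smoothed_{sample}.tsv", sep="\t")
        calls = cnvr_mod.call_cores(
            probes,
            sample,
            genome,
            threshold=cc.threshold,
            min_probes=cc.min_probes,
            flank=cc.flank,
            max_gap=cc.max_gap or None,
        )
        per_sample.append(calls)
        path = outdir / f"cnvr_{sample}.bed"
        cnvr_mod.write_bed(calls, path, score_from="mean_m")
        outputs.append(path)
        log.info("call %s: %d CNVRs", sample, len(calls))
    nonred = cnvr_mod.merge_to_nonredundant(per_sample, genome)
    bed = outdir / "cnvr_nonredundant.bed"
    cnvr_mod.write_bed(nonred, bed)
    tsv = outdir / "cnvr_nonredundant.tsv"
    nonred.to_csv(tsv, sep="\t", index=False, float_format=FLOAT_FMT)
    log.info("call: %d non-redundant CNVRs", len(nonred))
    return outputs + [bed, tsv]


def stage_annotate(config: PipelineConfig, outdir: Path) -> list[Path]:
    genome = GenomeModel.read(outdir / "genome")
    nonred = pd.read_csv(outdir / "cnvr_nonredundant.tsv", sep="\t")
    genes = intervals.merge_intervals(intervals.IntervalSet.from_frame(genome.features["genes"]))
    table = intervals.coverage_table(nonred, genes, genome)
    by_status = intervals.genes_overlapping(nonred, genome.features["genes"])
    outputs = []
    path = outdir / "coverage_table.tsv"
    table.to_csv(path, sep="\t", index=False, float_format="%.2f")
    outputs.append(path)
    for status, ids in by_status.items():
        p = outdir / f"cnv_genes_{status}.txt"
        p.write_text("\n".join(ids) + ("\n" if ids else ""))
        outputs.append(p)
    log.info(
        "annotate: %d gain / %d loss CNV genes",
        len(by_status["gain"]), len(by_status["loss"]),
    )
    return outputs


def stage_permtest(config: PipelineConfig, outdir: Path) -> list[Path]:
    genome = GenomeModel.read(outdir / "genome")
    nonred = pd.read_csv(outdir / "cnvr_nonredundant.tsv", sep="\t")
    query = intervals.IntervalSet.from_frame(nonred[["chrom", "start", "end"]])
    results = {}
    for feature_set in ("genes", "ucsc_elements"):
        fs = intervals.merge_intervals(
            intervals.IntervalSet.from_frame(genome.features[feature_set])
        )
        res = intervals.random_interval_test(
            query,
            fs,
            genome,
            n_rounds=config.permtest.n_rounds,
            tail="depletion",
            seed=_subseed(config.seed, f"permtest:{feature_set}"),
        )
        results[feature_set] = res.to_dict()
        log.info(
            "permtest %s: observed %.0f expected %.0f p=%.4g",
            feature_set, res.observed, res.expected, res.p_value,
        )
    path = outdir / "permtest.json"
    path.write_text(json.dumps(results, indent=2) + "\n")
    tsv = outdir / "permtest.tsv"
    pd.DataFrame(results).T.rename_axis("features").reset_index().to_csv(
        tsv, sep="\t", index=False, float_format="%.6g"
    )
    return [path, tsv]


def stage_enrich(config: PipelineConfig, outdir: Path) -> list[Path]:
    genome = GenomeModel.read(outdir / "genome")
    universe = set(genome.features["genes"]["id"])
    cnv_genes = set()
    for status in ("gain", "loss"):
        p = outdir / f"cnv_genes_{status}.txt"
        cnv_genes |= set(p.read_text().split())
    rng = np.random.default_rng(_subseed(config.seed, "genesets"))
    ec = config.enrich
    uni = sorted(universe)
    sets = {}
    for i in range(ec.n_random_sets):
        size = min(int(rng.integers(ec.set_size_min, ec.set_size_max + 1)), len(uni))
        sets[f"pathway{i:02d}"] = set(rng.choice(uni, size=size, replace=False))
    if cnv_genes:
        size = min(max(int(rng.integers(ec.set_size_min, ec.set_size_max + 1)), 10), len(uni))
        n_spike = min(int(round(ec.spike_fraction * size)), len(cnv_genes))
        spiked = set(rng.choice(sorted(cnv_genes), size=n_spike, replace=False))
        rest = sorted(universe - spiked)
        spiked |= set(rng.choice(rest, size=min(size - n_spike, len(rest)), replace=False))
        sets["disease_related"] = spiked
    collection = enrich.GeneSetCollection(universe=universe, sets=sets)
    collection.write_gmt(outdir / "genesets.gmt")
    results = enrich.enrich_sets(cnv_genes, collection)
    path = outdir / "enrichment.tsv"
    results.to_csv(path, sep="\t", index=False, float_format="%.6g")
    top = results.iloc[0] if len(results) else None
    if top is not None:
        log.info("enrich: top set %s (fdr=%.3g)", top["set_name"], top["fdr"])
    return [outdir / "genesets.gmt", path]


def simulate_expression(
    genes: list[str],
    cnv_status: dict[str, str],
    de_cfg: DEConfig,
    seed: int,
) -> expression.ExpressionMatrix:
    """Synthetic probeset-level expression with CNV-linked shifts.

    Each gene gets 1-3 probesets; CNV genes shift their test-group mean by
    ``effect_log2`` in the copy-number direction with probability
    ``consistent_fraction`` (opposite direction otherwise), emulating the
    partial concordance between copy number and expression.
    """
    rng = np.random.default_rng(seed)
    samples = [f"T{i}" for i in range(de_cfg.n_test)] + [
        f"C{i}" for i in range(de_cfg.n_control)
    ]
    groups = pd.Series(
        ["test"] * de_cfg.n_test + ["control"] * de_cfg.n_control, index=samples
    )
    rows = {}
    mapping = {}
    for gene in genes:
        shift = 0.0
        if gene in cnv_status:
            sign = 1.0 if cnv_status[gene] == "gain" else -1.0
            if rng.random() >= de_cfg.consistent_fraction:
                sign = -sign
            shift = sign * de_cfg.effect_log2
        base = rng.normal(8.0, 1.0)
        for p in range(int(rng.integers(1, 4))):
            pid = f"{gene}_at{p}"
            mapping[pid] = gene
            mu = base + rng.normal(0, 0.2)
            vals = np.concatenate(
                [
                    mu + shift + rng.normal(0, de_cfg.noise_sd, de_cfg.n_test),
                    mu + rng.normal(0, de_cfg.noise_sd, de_cfg.n_control),
                ]
            )
            rows[pid] = np.exp2(vals)
    X = pd.DataFrame(rows, index=samples).T
    return expression.ExpressionMatrix(
        intensities=X, probeset_to_gene=pd.Series(mapping), groups=groups
    )


def stage_de(config: PipelineConfig, outdir: Path) -> list[Path]:
    genome = GenomeModel.read(outdir / "genome")
    status: dict[str, str] = {}
    seen_both = set()
    for s in ("gain", "loss"):
        for g in (outdir / f"cnv_genes_{s}.txt").read_text().split():
            if g in status:
                seen_both.add(g)
            status[g] = s
    for g in seen_both:  # ambiguous direction: excluded from consistency
        del status[g]
    genes = sorted(genome.features["genes"]["id"])
    matrix = simulate_expression(genes, status, config.de, _subseed(config.seed, "expression"))
    collapsed = expression.collapse_probesets(matrix)
    de = expression.de_test(
        collapsed, matrix.groups, fdr_threshold=config.de.fdr_threshold
    )
    consistency = expression.consistency_call(status, de)
    outputs = []
    for name, obj in (("de.tsv", de.reset_index()), ("consistency.tsv", consistency.reset_index())):
        path = outdir / name
        obj.to_csv(path, sep="\t", index=False, float_format="%.6g")
        outputs.append(path)
    n_cons = int((consistency["label"] == "consistent").sum())
    log.info("de: %d/%d CNV genes consistent", n_cons, len(consistency))
    return outputs


STAGES = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "correct": stage_correct,
    "segment": stage_segment,
    "call": stage_call,
    "annotate": stage_annotate,
    "permtest": stage_permtest,
    "enrich": stage_enrich,
    "de": stage_de,
}


def run_all(config: PipelineConfig, outdir: str | Path) -> RunManifest:
    """Execute every stage in order; abort on failure naming the stage."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config.seed)
    order = ["simulate", "preprocess", "correct", "segment", "call",
             "annotate", "permtest", "enrich", "de"]
    for name in order:
        if name == "simulate" and not config.simulate.enabled:
            continue
        if name == "enrich" and not config.enrich.enabled:
            continue
        if name == "de" and not config.de.enabled:
            continue
        t0 = time.time()
        section = getattr(config, name, None)
        params = dataclasses.asdict(section) if dataclasses.is_dataclass(section) else {}
        try:
            outputs = STAGES[name](config, outdir)
        except Exception as exc:
            manifest.write(outdir / "manifest.json")
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        manifest.record(name, params, outputs, t0)
        manifest.write(outdir / "manifest.json")
    return manifest
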