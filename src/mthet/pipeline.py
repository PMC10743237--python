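"""End-to-end orchestration of the heteroplasmy analysis on synthetic data.

The pipeline chains: admixture cutoff determination -> per-sample variant
calling with site filters and indel blacklist -> region/effect annotation
and deleterious counting -> qPCR copy-number estimation -> ordered-stage
trend statistics. Every stage's output is serialized under the output
directory, and a manifest records the seed and configuration so a rerun
reproduces every stochastic output exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .admixture import run_admixture_experiment
from .annotate import annotate_variants, deleterious_burden
from .calling import (
    CallerConfig,
    apply_indel_blacklist,
    apply_site_filters,
    call_indels,
    call_snvs,
)
from .copynumber import CtRecord, mtdna_cn, normalize_burden
from .errors import MthetError, StageError
from .io import write_calls_tsv, write_variants_vcf
from .reference import load_pathogenicity, load_toy_regions
from .simulate import (
    BurdenModel,
    CopyNumberModel,
    attach_cohort_pileups,
    cohort_to_frame,
    random_genome,
    simulate_admixture_pair,
    simulate_cohort,
)
from .stats import OrderedGroups, dunnett_many_to_one, jonckheere_terpstra


@dataclass
class PipelineConfig:
    """Configuration of the demo pipeline (toy-genome scale by default)."""

    seed: int = 0
    outdir: str = "mthet_out"
    genome_length: int = 2000
    admixture_depth: int = 30_000
    admixture_error_rate: float = 5e-4
    admixture_ratios: tuple[float, ...] = (0.02, 0.01, 0.005, 0.0025)
    n_per_stage: dict = field(
        default_factory=lambda: {"G1": 16, "G2": 15, "G4": 4, "G5": 42}
    )
    cohort_depth: int = 3_000
    burden_baseline: float = 0.3
    burden_increment: float = 0.5
    cn_baseline: float = 1500.0
    cn_decrement: float = 250.0
    cn_noise_sd: float = 0.3
    fallback_cutoff: float = 0.005
    write_vcfs: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        return cfg


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _regions_for_length(genome_length: int):
    """The packaged toy layout, clipped and gap-filled to the configured
    genome length (the demo pipeline runs on toy-scale genomes)."""
    from .reference import build_region_table

    toy = load_toy_regions()
    features, strands = [], {}
    for r in toy.regions:
        if r.region_type.value == "intergenic" or r.start > genome_length:
            continue
        features.append((r.start, min(r.end, genome_length), r.region_type, r.name))
        strands[r.name] = r.strand
    return build_region_table(features, genome_length, add_dloop=False, strands=strands)


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the report dict (also written to disk)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed, "stages": {}}
    rng = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in rng.spawn(4)]

    # --- stage: simulate + threshold -------------------------------------
    try:
        genome = random_genome(config.genome_length, seed=seeds[0])
        background, spike, private = simulate_admixture_pair(
            genome,
            mean_depth=config.admixture_depth,
            error_rate=config.admixture_error_rate,
            seed=seeds[0],
        )
        adm = run_admixture_experiment(
            background, spike, private, list(config.admixture_ratios), seed=seeds[1]
        )
        adm.to_json(out / "admixture.json")
        cutoff = adm.selected_cutoff or config.fallback_cutoff
        report["stages"]["threshold"] = adm.to_dict()
    except MthetError as e:
        raise StageError("threshold", str(e)) from e

    # --- stage: cohort simulation + calling + annotation ------------------
    try:
        regions = _regions_for_length(config.genome_length)
        ptable = load_pathogenicity()
        cohort = simulate_cohort(
            n_per_stage=config.n_per_stage,
            burden_model=BurdenModel(config.burden_baseline, config.burden_increment),
            cn_model=CopyNumberModel(
                config.cn_baseline, config.cn_decrement, config.cn_noise_sd
            ),
            seed=seeds[2],
        )
        attach_cohort_pileups(
            cohort, genome, regions, mean_depth=config.cohort_depth, seed=seeds[2]
        )
        cohort_to_frame(cohort).to_csv(out / "cohort.csv", index=False)

        caller = CallerConfig(min_vaf=cutoff)
        all_calls = []
        for s in cohort:
            calls = call_snvs(s.pileup, caller, s.sample_id) + call_indels(
                s.pileup, caller, s.sample_id
            )
            all_calls.extend(calls)
        all_calls = apply_site_filters(all_calls)
        all_calls = apply_indel_blacklist(all_calls, n_samples=len(cohort))
        write_calls_tsv(all_calls, out / "calls.tsv")
        if config.write_vcfs:
            vcf_dir = out / "vcf"
            vcf_dir.mkdir(exist_ok=True)
            for s in cohort:
                write_variants_vcf(
                    [c for c in all_calls if c.sample_id == s.sample_id],
                    vcf_dir / f"{s.sample_id}.vcf",
                    genome,
                )
        annotated = annotate_variants(all_calls, regions, genome, ptable)
        by_sample = {s.sample_id: [] for s in cohort}
        for v in annotated:
            by_sample[v.sample_id].append(v)
        burden = deleterious_burden(
            [(sid, vs) for sid, vs in by_sample.items()], vaf_window=(cutoff, 0.95)
        )
        report["stages"]["calling"] = {
            "n_calls": len(all_calls),
            "n_pass": sum(c.is_pass for c in all_calls),
            "cutoff": cutoff,
        }
    except MthetError as e:
        raise StageError("calling", str(e)) from e

    # --- stage: copy number ----------------------------------------------
    try:
        cn = {
            s.sample_id: mtdna_cn(CtRecord(s.sample_id, s.ct_nd1, s.ct_ppia))
            for s in cohort
        }
        normalized = {
            sid: normalize_burden(burden[sid], cn[sid], per=1000.0) for sid in cn
        }
        report["stages"]["copy_number"] = {"mean_cn": float(np.mean(list(cn.values())))}
    except MthetError as e:
        raise StageError("copy_number", str(e)) from e

    # --- stage: cohort statistics ----------------------------------------
    try:
        stage_order = [
            s for s in ("G1", "G2", "G4", "G5") if config.n_per_stage.get(s, 0) > 0
        ]
        burden_groups = OrderedGroups.from_pairs(
            stage_order, [(s.ckd_stage, burden[s.sample_id]) for s in cohort]
        )
        cn_groups = OrderedGroups.from_pairs(
            stage_order, [(s.ckd_stage, cn[s.sample_id]) for s in cohort]
        )
        jt_burden = jonckheere_terpstra(burden_groups, alternative="increasing")
        jt_cn = jonckheere_terpstra(cn_groups, alternative="decreasing")
        try:
            dunnett_cn = dunnett_many_to_one(cn_groups, control=stage_order[0], seed=seeds[3])
        except MthetError:
            dunnett_cn = {}
        report["stages"]["stats"] = {
            "jt_burden_increasing": {"J": jt_burden[0], "p": jt_burden[1]},
            "jt_cn_decreasing": {"J": jt_cn[0], "p": jt_cn[1]},
            "dunnett_cn_vs_G1": dunnett_cn,
            "normalized_burden_mean_per_1000": float(np.mean(list(normalized.values()))),
        }
    except MthetError as e:
        raise StageError("stats", str(e)) from e

    report["manifest"] = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "inputs": {p.name: _digest(p) for p in sorted(out.glob("*.csv"))},
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
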