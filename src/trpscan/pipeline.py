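"""End-to-end pipeline: simulate -> seed extraction -> subfamily detection ->
model building -> benchmark -> census classification -> redundancy
clustering -> repeat annotation -> specificity analysis.

One top-level seed deterministically derives every stage seed (stage seeds
are ``seed + fixed offset``, all below 2**31); no stage consumes unseeded
randomness, so rerunning with the same config reproduces byte-identical
artifacts.  Every run writes a manifest embedding the fully resolved config,
the derived seeds and the SHA-256 of each artifact.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import classify as _classify
from . import redundancy as _redundancy
from . import repeats as _repeats
from . import specificity as _specificity
from . import subfamilies as _subfamilies
from .io import ProteinRecord, write_alignment, write_fasta
from .profiles import extract_tm_region, save_models
from .synthetic import (
    GroundTruth,
    SyntheticConfig,
    channel_alignment,
    fragment_records,
    generate_pushpull_default,
    generate_superfamily,
    generate_unit_alignment,
)
from .subfamilies import build_subfamily_models, detect_subfamilies, select_major_subfamilies
from .profiles import build_profile, calibrate

log = logging.getLogger("trpscan")

STAGES = (
    "simulate",
    "seeds",
    "build",
    "benchmark",
    "classify",
    "cluster",
    "repeats",
    "specificity",
)

# fixed per-stage seed offsets derived from the single top-level seed
_STAGE_SEED_OFFSET = {name: 101 * (k + 1) for k, name in enumerate(STAGES)}


class PipelineError(RuntimeError):
    pass


@dataclasses.dataclass
class PipelineConfig:
    rng_seed: int = 0
    profile: str = "census"  # threshold profile for the census scan
    stages: tuple[str, ...] = STAGES
    synthetic: SyntheticConfig = dataclasses.field(default_factory=SyntheticConfig)
    train_fraction: float = 0.5
    min_fraction: float = 0.05  # "large subfamily" size threshold
    clustering_threshold: float = 80.0
    min_repeats: int = 27  # fragmented-model flag boundary
    n_permutations: int = 1000
    z_threshold: float = 3.0
    tm_flank: int = 20
    fragment_fraction: float = 0.1
    calibration_samples: int = 200

    def validate(self) -> None:
        if self.profile not in _classify.THRESHOLD_PROFILES:
            raise PipelineError(
                f"unknown threshold profile {self.profile!r}; "
                f"known: {sorted(_classify.THRESHOLD_PROFILES)}"
            )
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise PipelineError(f"unknown stages: {sorted(unknown)}")
        self.synthetic.validate()

    def stage_seed(self, stage: str) -> int:
        return (self.rng_seed + _STAGE_SEED_OFFSET[stage]) % (2**31)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        syn = SyntheticConfig(**raw.pop("synthetic", {}))
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        cfg = cls(synthetic=syn, **raw)
        return cfg

    def resolved(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["synthetic"].pop("background", None)
        d["stage_seeds"] = {s: self.stage_seed(s) for s in self.stages}
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute the enabled stages and write artifacts plus a manifest.

    A stage failure writes a FAILED marker naming the stage and re-raises.
    """
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": config.resolved(),
        "stages": {},
        "artifacts": {},
    }
    state: dict[str, Any] = {}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.time()
        log.info("stage %s: start", stage)
        try:
            _STAGE_FUNCS[stage](config, out, state)
        except Exception as exc:
            (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
            raise PipelineError(f"stage {stage} failed: {exc}") from exc
        manifest["stages"][stage] = {
            "seed": config.stage_seed(stage),
            "seconds": round(time.time() - t0, 3),
        }
        log.info("stage %s: done in %.1fs", stage, time.time() - t0)
    for p in sorted(out.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest["artifacts"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------


def _stage_simulate(cfg: PipelineConfig, out: Path, state: dict) -> None:
    syn = dataclasses.replace(cfg.synthetic, rng_seed=cfg.stage_seed("simulate"))
    records, truth = generate_superfamily(syn)
    records = fragment_records(
        records, truth, cfg.fragment_fraction, cfg.stage_seed("simulate") + 7
    )
    unit_aln = generate_unit_alignment(syn)
    pp_aln, pp_truth = generate_pushpull_default(cfg.stage_seed("simulate") + 13)
    write_fasta(records, out / "records.fasta")
    write_alignment(unit_aln, out / "ankyrin_units.fasta")
    write_alignment(pp_aln, out / "pushpull.fasta")
    truth.to_tsv(out / "truth.tsv")
    pp_truth.site_plan_to_json(out / "pushpull_sites.json")
    state.update(
        syn=syn, records=records, truth=truth,
        unit_aln=unit_aln, pp_aln=pp_aln, pp_truth=pp_truth,
    )


def _stage_seeds(cfg: PipelineConfig, out: Path, state: dict) -> None:
    truth: GroundTruth = state["truth"]
    lines = ["protein_id\ttm_start\ttm_end\tn_helices"]
    seen: set[str] = set()
    for rec in state["records"]:
        fam = truth.family_of.get(rec.id, "decoy")
        if fam == "decoy" or fam in seen:
            continue
        seen.add(fam)
        region = extract_tm_region(rec.seq, flank=cfg.tm_flank)
        if region is None:
            lines.append(f"{rec.id}\t.\t.\t0")
        else:
            lines.append(f"{rec.id}\t{region.start}\t{region.end}\t{len(region.helices)}")
    (out / "tm_seeds.tsv").write_text("\n".join(lines) + "\n")


def _split(ids: list[str], fraction: float) -> tuple[list[str], list[str]]:
    k = int(round(len(ids) * fraction))
    return ids[:k], ids[k:]


def _stage_build(cfg: PipelineConfig, out: Path, state: dict) -> None:
    records, truth = state["records"], state["truth"]
    members_by_family: dict[str, list[str]] = {}
    for rec in records:
        fam = truth.family_of[rec.id]
        if fam != "decoy":
            members_by_family.setdefault(fam, []).append(rec.id)
    train_ids: list[str] = []
    test_ids: list[str] = []
    for fam in sorted(members_by_family):
        tr, te = _split(members_by_family[fam], cfg.train_fraction)
        train_ids += tr
        test_ids += te
    train_aln = channel_alignment(records, truth, include=train_ids)
    partition = detect_subfamilies(train_aln)
    selected, coverage = select_major_subfamilies(partition, cfg.min_fraction)
    log.info("detected %d major subfamilies covering %.1f%%", len(selected), 100 * coverage)
    models, unspecific = build_subfamily_models(
        train_aln, partition, selected,
        calibration_samples=cfg.calibration_samples,
        rng_seed=cfg.stage_seed("build"),
    )
    # name each detected cluster after its majority ground-truth family
    for m in models:
        fams = [truth.family_of[s] for s in partition.members(m.name)]
        m.name = max(set(fams), key=fams.count)
    save_models(models + [unspecific], out / "models.jsonl")
    _subfamilies.partition_to_tsv(partition, out / "partition.tsv")
    _subfamilies.trajectory_to_tsv(partition, out / "cost_trajectory.tsv")
    state.update(models=models, unspecific=unspecific, test_ids=test_ids, partition=partition)


def _stage_benchmark(cfg: PipelineConfig, out: Path, state: dict) -> None:
    records, truth = state["records"], state["truth"]
    held_out = [r for r in records if r.id in set(state["test_ids"])]
    results = _classify.classify_records(
        state["models"], state["unspecific"], held_out, profile=cfg.profile
    )
    report = _classify.benchmark(results, truth.family_of)
    report.to_csv(out / "benchmark.tsv", sep="\t", index=False)
    macro = report[report["family"] == "macro"].iloc[0]
    (out / "benchmark_summary.txt").write_text(
        f"held-out records: {len(held_out)}\n"
        f"macro sensitivity: {100 * macro['sensitivity']:.1f}%\n"
        f"macro selectivity: {100 * macro['selectivity']:.1f}%\n"
    )
    state["benchmark"] = report


def _stage_classify(cfg: PipelineConfig, out: Path, state: dict) -> None:
    records = state["records"]
    results = _classify.classify_records(
        state["models"], state["unspecific"], records, profile=cfg.profile
    )
    _classify.verdicts_to_tsv(results, out / "verdicts.tsv")
    state["verdicts"] = results


def _stage_cluster(cfg: PipelineConfig, out: Path, state: dict) -> None:
    records, truth = state["records"], state["truth"]
    by_id = {r.id: r for r in records}
    channel_regions = []
    for res in state.get("verdicts", []):
        if res.verdict in ("unclassified", "excluded") or res.best_hit is None:
            continue
        rec = by_id[res.protein_id]
        h = res.best_hit
        channel_regions.append(
            ProteinRecord(res.protein_id, rec.seq[h.envelope_start - 1 : h.envelope_end])
        )
    clusters = _redundancy.greedy_cluster(channel_regions, cfg.clustering_threshold)
    _redundancy.clusters_to_tsv(clusters, out / "clusters.tsv")
    write_fasta(
        _redundancy.extract_centroids(clusters, channel_regions), out / "centroids.fasta"
    )
    state["clusters"] = clusters


def _stage_repeats(cfg: PipelineConfig, out: Path, state: dict) -> None:
    records, truth = state["records"], state["truth"]
    unit_model = build_profile(state["unit_aln"], name="ankyrin_unit")
    calibrate(
        unit_model,
        n_samples=cfg.calibration_samples,
        rng_seed=cfg.stage_seed("repeats"),
    )
    verdict_of = {r.protein_id: r.verdict for r in state.get("verdicts", [])}
    annotations = []
    lines = ["protein_id\tverdict\tankyrin_count\tplanted\tfragmented_flag"]
    for rec in records:
        fam = truth.family_of[rec.id]
        if truth.repeat_count_of.get(rec.id, 0) == 0 and fam != "fam_N":
            continue
        ann = _repeats.count_repeats(rec, unit_model)
        verdict = verdict_of.get(rec.id, fam)
        flag = _repeats.flag_fragmented(verdict, ann, cfg.min_repeats)
        annotations.append(ann)
        lines.append(
            f"{rec.id}\t{verdict}\t{ann.ankyrin_count}\t"
            f"{truth.repeat_count_of.get(rec.id, 0)}\t{int(flag)}"
        )
    (out / "repeats.tsv").write_text("\n".join(lines) + "\n")
    _repeats.annotations_to_bed(annotations, out / "domains.bed.tsv")
    state["annotations"] = annotations


def _stage_specificity(cfg: PipelineConfig, out: Path, state: dict) -> None:
    pp_aln, pp_truth = state["pp_aln"], state["pp_truth"]
    report = _specificity.analyse(
        pp_aln,
        pp_truth.group_of,
        n_permutations=cfg.n_permutations,
        z_threshold=cfg.z_threshold,
        rng_seed=cfg.stage_seed("specificity"),
    )
    report.to_tsv(out / "specificity.tsv")
    report.calls_to_tsv(out / "query_calls.tsv")
    state["specificity"] = report


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "seeds": _stage_seeds,
    "build": _stage_build,
    "benchmark": _stage_benchmark,
    "classify": _stage_classify,
    "cluster": _stage_cluster,
    "repeats": _stage_repeats,
    "specificity": _stage_specificity,
}
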