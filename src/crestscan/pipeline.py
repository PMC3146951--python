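"""End-to-end orchestration: generate -> topology -> filter -> scan ->
classify -> evaluate, as one reproducible run.

A run is driven by a :class:`RunConfig` (every field defaulted; a fully
default config runs end-to-end on generated data) and a single seed. The
seed fans out into per-stage seeds by stable hashing of the stage name, so
stages can be re-run independently yet reproducibly. All tabular outputs
carry provenance comments (tool version, resolved-config hash, seed) and no
timestamps, so identical config + seed gives byte-identical calls and
reports; wall-clock information goes to the log only.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import __version__
from .constellation import EvaluationReport, classify_protein, evaluate
from .hydropathy import HydropathyConfig, predict_tm
from .io_formats import (ProteinRecord, Topology, write_calls, write_fasta,
                         write_topology_table)
from .motifs import ScanConfig
from .redundancy import dedupe, group_by_coverage, remove_fragments
from .synthetic import GeneratorSpec, generate_dataset

logger = logging.getLogger("crestscan")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and its inputs."""


@dataclass(frozen=True)
class FilterConfig:
    min_len: int = 100
    identity_threshold: float = 0.95
    score_per_column_min: float = 1.0
    length_coverage_min: float = 0.5

    def __post_init__(self):
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if not (0.0 <= self.identity_threshold <= 1.0):
            raise ValueError("identity_threshold must be in [0, 1]")
        if not (0.0 <= self.length_coverage_min <= 1.0):
            raise ValueError("length_coverage_min must be in [0, 1]")


@dataclass(frozen=True)
class RunConfig:
    """All knobs of one pipeline run; every field has a default."""

    seed: int = 0
    n_per_class: int = 10
    topology_source: str = "planted"  # or "predicted"
    log_level: str = "INFO"
    generator: GeneratorSpec = field(default_factory=GeneratorSpec)
    hydropathy: HydropathyConfig = field(default_factory=HydropathyConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)

    def __post_init__(self):
        if self.topology_source not in ("planted", "predicted"):
            raise ValueError(
                f"topology_source must be 'planted' or 'predicted', "
                f"got {self.topology_source!r}"
            )
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")


_SECTIONS = {
    "generator": GeneratorSpec,
    "hydropathy": HydropathyConfig,
    "scan": ScanConfig,
    "filter": FilterConfig,
}
_TUPLE_FIELDS = {"tm_length_range", "loop_length_range"}


def config_from_dict(data: Mapping) -> RunConfig:
    """Build a validated RunConfig from a nested mapping; unknown keys error."""
    data = dict(data or {})
    kwargs: dict = {}
    for section, cls in _SECTIONS.items():
        if section in data:
            sub = dict(data.pop(section) or {})
            known = {f.name for f in dataclasses.fields(cls)}
            unknown = set(sub) - known
            if unknown:
                raise ValueError(
                    f"unknown key(s) in section {section!r}: {sorted(unknown)}"
                )
            for key in _TUPLE_FIELDS & set(sub):
                sub[key] = tuple(sub[key])
            if "scale" in sub and sub["scale"] is not None:
                sub["scale"] = dict(sub["scale"])
            kwargs[section] = cls(**sub)
    top_known = {"seed", "n_per_class", "topology_source", "log_level"}
    unknown = set(data) - top_known
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
    kwargs.update(data)
    return RunConfig(**kwargs)


def config_from_file(path: str | Path) -> RunConfig:
    with Path(path).open("r", encoding="utf-8") as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def config_to_dict(config: RunConfig) -> dict:
    """Resolved config with all defaults materialised, YAML/JSON-safe."""
    def clean(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: clean(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)}
        if isinstance(obj, Mapping):
            return {k: clean(v) for k, v in sorted(obj.items())}
        if isinstance(obj, tuple):
            return [clean(v) for v in obj]
        return obj
    out = {"seed": config.seed, "n_per_class": config.n_per_class,
           "topology_source": config.topology_source,
           "log_level": config.log_level}
    for section in _SECTIONS:
        out[section] = clean(getattr(config, section))
    return out


def config_hash(config: RunConfig) -> str:
    canonical = yaml.safe_dump(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed (< 2**31) derived from the global seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def version_stamp(config: RunConfig) -> list[str]:
    """Provenance comment lines embedded in every tabular output header."""
    return [
        f"crestscan v{__version__}",
        f"config_sha256={config_hash(config)}",
        f"seed={config.seed}",
    ]


@dataclass(frozen=True)
class RunResult:
    outdir: Path
    report: EvaluationReport
    n_generated: int
    n_filtered: int
    predicted_labels: Mapping[str, str]


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %-12s done in %.2fs", name,
                        time.perf_counter() - t0)
            return out
        return inner
    return wrap


def run_all(config: RunConfig | None = None,
            outdir: str | Path = "crestscan_run") -> RunResult:
    """Execute the full pipeline into ``outdir`` and return the evaluation.

    Writes: the generated dataset (FASTA, planted topology TSV, truth JSON),
    the topology actually used, the filtered FASTA and cluster table, all
    constellation calls, per-protein classifications, the evaluation report,
    coverage groups of the positive calls, the resolved config snapshot and
    a log file.
    """
    config = config or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = version_stamp(config)

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.log_level)
    try:
        (outdir / "config.yaml").write_text(
            "".join(f"# {c}\n" for c in stamp)
            + yaml.safe_dump(config_to_dict(config), sort_keys=True),
            encoding="utf-8",
        )

        dataset = _stage("generate")(generate_dataset)(
            config.n_per_class, spec=config.generator,
            seed=stage_seed(config.seed, "generate"), outdir=outdir,
            comments=stamp,
        )

        @_stage("topology")
        def _topology() -> dict[str, Topology]:
            if config.topology_source == "planted":
                return dict(dataset.topologies)
            topo = {rec.id: predict_tm(rec, config.hydropathy)
                    for rec in dataset.records}
            write_topology_table(outdir / "predicted_topology.tsv", topo,
                                 comments=stamp)
            return topo
        topologies = _topology()

        @_stage("filter")
        def _filter() -> list[ProteinRecord]:
            kept = remove_fragments(dataset.records, config.filter.min_len)
            reps, assignments = dedupe(kept,
                                       config.filter.identity_threshold)
            write_fasta(outdir / "filtered.fasta", reps)
            with (outdir / "clusters.tsv").open("w") as fh:
                for c in stamp:
                    fh.write(f"# {c}\n")
                fh.write("representative_id\tmember_id\n")
                for a in assignments:
                    for m in a.member_ids:
                        fh.write(f"{a.representative_id}\t{m}\n")
            return reps
        filtered = _filter()

        @_stage("scan")
        def _scan():
            calls, labels = [], {}
            for rec in sorted(filtered, key=lambda r: r.id):
                topo = topologies.get(rec.id, Topology(protein_id=rec.id))
                label, rec_calls = classify_protein(rec, topo, config.scan)
                labels[rec.id] = label
                calls.extend(rec_calls)
            write_calls(outdir / "calls.tsv", calls, comments=stamp)
            with (outdir / "classifications.tsv").open("w") as fh:
                for c in stamp:
                    fh.write(f"# {c}\n")
                fh.write("protein_id\tcall\n")
                for pid in sorted(labels):
                    fh.write(f"{pid}\t{labels[pid]}\n")
            return calls, labels
        calls, predicted_labels = _scan()

        @_stage("evaluate")
        def _evaluate() -> EvaluationReport:
            truth = {pid: t.label for pid, t in dataset.truths.items()
                     if pid in predicted_labels}
            report = evaluate(truth, predicted_labels)
            payload = {
                "provenance": stamp,
                "topology_source": config.topology_source,
                "evaluation": report.to_dict(),
            }
            (outdir / "report.json").write_text(
                json.dumps(payload, indent=2) + "\n", encoding="ascii")
            return report
        report = _evaluate()

        @_stage("group")
        def _group() -> None:
            positives = [r for r in filtered
                         if predicted_labels[r.id] == "positive"]
            groups = (group_by_coverage(
                positives, config.filter.score_per_column_min,
                config.filter.length_coverage_min) if positives else [])
            with (outdir / "candidate_groups.tsv").open("w") as fh:
                for c in stamp:
                    fh.write(f"# {c}\n")
                fh.write("group_representative\tmember_id\n")
                for g in groups:
                    for m in g.member_ids:
                        fh.write(f"{g.representative_id}\t{m}\n")
        _group()

        return RunResult(outdir=outdir, report=report,
                         n_generated=len(dataset.records),
                         n_filtered=len(filtered),
                         predicted_labels=predicted_labels)
    finally:
        logger.removeHandler(handler)
        handler.close()
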