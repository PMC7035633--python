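"""End-to-end orchestration: evidence -> loci -> cutoffs -> calls -> reports.

Each stage is runnable on its own through the library functions it
wraps; :func:`run_pipeline` chains them with fixed output names and a
machine-readable run log holding parameter values and per-stage read
and locus counts, so a run can be audited and reproduced.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import formats_io
from .annotator import KnownLociDB, annotate
from .cohort_analysis import trio_report
from .cutoff_selector import (
    PresenceMatrix,
    call_presence,
    overall_sensitivity,
    select_cutoffs,
    sensitivity_grid,
)
from .formats_io import GenomicInterval, ManifestEntry
from .locus_caller import (
    CandidateLocus,
    SampleLibrary,
    call_loci,
    cluster_reads,
    total_mapped,
)
from .read_filtering import (
    DEFAULT_BIT_CUTOFFS,
    MEFamily,
    ReadPairEvidence,
    best_flank_alignments,
    filter_flank_mq,
    filter_me_reads,
    join_pairs,
)

__all__ = [
    "RunConfig",
    "SampleResult",
    "process_sample",
    "call_cohort",
    "run_pipeline",
    "validate_config",
]


@dataclass
class RunConfig:
    manifest: str
    output_dir: str
    families: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BIT_CUTOFFS)
    )
    window: int = 500
    min_mq: int = 30
    grid_max: int = 10
    sensitivity_target: float = 0.90
    match_tol: int = 100
    tpm_denominator: str = "mapped-filtered"
    seed: int = 0
    fixed_truth_bed: str | None = None
    reference_mei_bed: str | None = None
    polymorphic_mei_bed: str | None = None
    gene_gtf: str | None = None
    segmentation_bed: str | None = None
    pedigree: str | None = None
    log_level: str = "INFO"


@dataclass
class SampleResult:
    """One sample-library's filtered evidence plus stage accounting."""

    sample_id: str
    family: str
    evidence: list[ReadPairEvidence]
    total_mapped_reads: int
    stage_counts: dict[str, int]


def process_sample(
    entry: ManifestEntry,
    family: MEFamily,
    min_mq: int = 30,
    tpm_denominator: str = "mapped-filtered",
    base_dir: Path | None = None,
) -> SampleResult:
    """Run the read-level filters for one sample-library.

    ME Reads are thresholded at the family bit-score cutoff; Flanking
    Reads are reduced to one best position per read then MQ-filtered;
    the two are joined on read id. The TPM denominator is either the
    joined, fully filtered evidence count (``mapped-filtered``, the
    default, which makes TPM insensitive to junk alignments) or all
    mapped flanking reads (``mapped``).
    """
    base = base_dir or Path(".")
    blast_path = base / entry.blast6_path
    sam_path = base / entry.sam_path

    records = formats_io.read_blast6(blast_path)
    me_scores: dict[str, float] = {}
    for rec in records:
        prev = me_scores.get(rec.query_id)
        if prev is None or rec.bit_score > prev:
            me_scores[rec.query_id] = rec.bit_score
    me_pass = filter_me_reads(me_scores, family)

    alignments = formats_io.read_sam(sam_path, sample_id=entry.sample_id)
    mapped = [a for a in alignments if not a.is_unmapped]
    best = best_flank_alignments(mapped)
    mq_pass = filter_flank_mq(best, min_mq=min_mq)

    stage_counts = {
        "blast6_records": len(records),
        "me_reads_scored": len(me_scores),
        "me_reads_pass": len(me_pass),
        "sam_alignments": len(alignments),
        "flank_mapped_reads": len(best),
        "flank_mq_pass": len(mq_pass),
    }
    evidence = join_pairs(
        me_pass, mq_pass, family, me_scores, stage_counts
    )
    if tpm_denominator == "mapped-filtered":
        denom = len(evidence)
    elif tpm_denominator == "mapped":
        denom = len(best)
    else:
        raise ValueError(
            "tpm_denominator must be 'mapped-filtered' or 'mapped'"
        )
    return SampleResult(
        sample_id=entry.sample_id,
        family=family.name,
        evidence=evidence,
        total_mapped_reads=denom,
        stage_counts=stage_counts,
    )


def call_cohort(
    entries: Sequence[ManifestEntry],
    family: MEFamily,
    window: int = 500,
    min_mq: int = 30,
    tpm_denominator: str = "mapped-filtered",
    base_dir: Path | None = None,
) -> tuple[list[CandidateLocus], dict[str, SampleLibrary], list[SampleResult]]:
    """Filter every sample of one family and cluster the pooled evidence.

    Clustering pools all samples so a shared insertion receives one
    locus id across the cohort.
    """
    fam_entries = [e for e in entries if e.family == family.name]
    results = [
        process_sample(e, family, min_mq, tpm_denominator, base_dir)
        for e in fam_entries
    ]
    libraries = {
        r.sample_id: SampleLibrary(
            sample_id=r.sample_id,
            family=family.name,
            total_mapped_reads=max(r.total_mapped_reads, 1),
        )
        for r in results
    }
    pooled = [ev for r in results for ev in r.evidence]
    clusters = cluster_reads(pooled, window=window)
    loci = call_loci(clusters, libraries, prefix=family.name)
    return loci, libraries, results


def _read_truth_bed(path: str | Path) -> dict[str, list[GenomicInterval]]:
    """Truth/reference BED keyed by family; fixed class only when present.

    Accepts both the simulator's extended truth BED (class column 7)
    and a plain BED whose name column is ``family:locus_id``.
    """
    by_family: dict[str, list[GenomicInterval]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                continue
            if len(fields) >= 7 and fields[6] != "fixed_reference":
                continue
            family = fields[3].split(":")[0]
            by_family.setdefault(family, []).append(
                GenomicInterval(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    label=family,
                    strand=fields[5] if len(fields) > 5 else None,
                )
            )
    return by_family


def run_pipeline(config: RunConfig) -> Path:
    """Run filter -> cluster -> cutoff -> call (-> annotate -> trio).

    Writes loci.bed, evidence.tsv, cutoffs.tsv, calls.vcf and, when the
    corresponding inputs are configured, annotation.tsv and
    trio_report.tsv, plus run_log.json with input checksums, parameters
    and per-stage counts.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = Path(config.manifest)
    entries = formats_io.read_manifest(manifest_path)
    base_dir = manifest_path.parent

    truth_by_family: dict[str, list[GenomicInterval]] = {}
    if config.fixed_truth_bed:
        truth_by_family = _read_truth_bed(base_dir / config.fixed_truth_bed
                                          if not Path(config.fixed_truth_bed).is_absolute()
                                          else config.fixed_truth_bed)

    all_loci: list[CandidateLocus] = []
    all_libraries: dict[str, SampleLibrary] = {}
    run_log: dict = {
        "parameters": {
            "window": config.window,
            "min_mq": config.min_mq,
            "grid_max": config.grid_max,
            "sensitivity_target": config.sensitivity_target,
            "match_tol": config.match_tol,
            "tpm_denominator": config.tpm_denominator,
            "seed": config.seed,
        },
        "inputs": {"manifest": _sha256(manifest_path)},
        "families": {},
    }
    cutoff_rows: list[str] = []
    matrices: list[PresenceMatrix] = []

    for name, bit_cutoff in config.families.items():
        if not any(e.family == name for e in entries):
            continue
        family = MEFamily(name=name, bit_cutoff=bit_cutoff)
        loci, libraries, results = call_cohort(
            entries, family, config.window, config.min_mq,
            config.tpm_denominator, base_dir,
        )
        fam_log: dict = {
            "n_loci": len(loci),
            "samples": {
                r.sample_id: r.stage_counts for r in results
            },
        }
        truth = truth_by_family.get(name, [])
        if truth:
            sens_at_selected: dict[str, float] = {}
            for sample_id, lib in libraries.items():
                grid = sensitivity_grid(
                    loci, truth, sample_id, name,
                    config.grid_max, config.match_tol,
                )
                t_cut, u_cut = select_cutoffs(
                    grid, config.sensitivity_target, config.grid_max
                )
                lib.tpm_cutoff = float(t_cut)
                lib.ur_cutoff = u_cut
                sens_at_selected[sample_id] = grid.at(t_cut, u_cut)
                cutoff_rows.append(
                    f"{sample_id}\t{name}\t{t_cut}\t{u_cut}\t"
                    f"{grid.at(t_cut, u_cut):.4f}"
                )
            fam_log["sensitivity_at_selected"] = sens_at_selected
        matrix = call_presence(loci, libraries)
        matrices.append(matrix)
        if truth:
            detected_ids = _match_truth_ids(
                loci, truth, config.match_tol, matrix
            )
            fam_log["overall_sensitivity"] = (
                len(detected_ids) / len(truth) if truth else None
            )
        run_log["families"][name] = fam_log
        all_loci.extend(loci)
        all_libraries.update(libraries)

        formats_io.write_vcf(
            loci, sorted(libraries), matrix, outdir / f"calls.{name}.vcf",
            families=[name],
        )
        if config.pedigree:
            trios = formats_io.read_pedigree(
                base_dir / config.pedigree
                if not Path(config.pedigree).is_absolute()
                else config.pedigree
            )
            reports = trio_report(matrix, trios, name)
            with open(outdir / f"trio_report.{name}.tsv", "w") as fh:
                fh.write(
                    "family_id\tme_family\tchild_loci\tviolations\t"
                    "error_rate\tsingle_parent_rate\tboth_parent_rate\n"
                )
                for r in reports:
                    fh.write(
                        f"{r.family_id}\t{r.me_family}\t"
                        f"{r.child_locus_count}\t{r.mendelian_violations}\t"
                        f"{r.inheritance_error_rate:.4f}\t"
                        f"{_fmt(r.single_parent_rate)}\t"
                        f"{_fmt(r.both_parent_rate)}\n"
                    )

    formats_io.write_bed(all_loci, outdir / "loci.bed")
    with open(outdir / "evidence.tsv", "w") as fh:
        fh.write("locus_id\tfamily\tsample_id\tread_count\ttpm\tur\n")
        for locus in all_loci:
            for sample_id in sorted(locus.per_sample):
                ev = locus.per_sample[sample_id]
                fh.write(
                    f"{locus.locus_id}\t{locus.family}\t{sample_id}\t"
                    f"{ev.read_count}\t{ev.tpm:.4f}\t{ev.ur}\n"
                )
    with open(outdir / "cutoffs.tsv", "w") as fh:
        fh.write("sample_id\tfamily\ttpm_cutoff\tur_cutoff\tsensitivity\n")
        fh.write("".join(row + "\n" for row in cutoff_rows))

    if config.reference_mei_bed or config.polymorphic_mei_bed:
        db = KnownLociDB(
            reference_meis=_load_bed(config.reference_mei_bed, base_dir),
            polymorphic_meis=_load_bed(config.polymorphic_mei_bed, base_dir),
        )
        gene_models = (
            formats_io.read_intervals(
                _resolve(config.gene_gtf, base_dir), "GTF"
            )
            if config.gene_gtf
            else []
        )
        segmentation = (
            formats_io.read_intervals(
                _resolve(config.segmentation_bed, base_dir), "BED"
            )
            if config.segmentation_bed
            else []
        )
        annotated = annotate(
            all_loci, db, gene_models, segmentation, config.match_tol
        )
        with open(outdir / "annotation.tsv", "w") as fh:
            fh.write(
                "locus_id\tfamily\tchrom\tposition\tstatus\t"
                "gene_context\tchromatin_state\n"
            )
            for a in annotated:
                fh.write(
                    f"{a.locus.locus_id}\t{a.locus.family}\t"
                    f"{a.locus.chrom}\t{a.locus.position}\t{a.status}\t"
                    f"{a.gene_context}\t{a.chromatin_state or '.'}\n"
                )

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2, sort_keys=True)
    return outdir


def _match_truth_ids(loci, truth, tol, matrix) -> set[int]:
    """Indices of truth intervals detected in at least one sample."""
    detected: set[int] = set()
    for i, interval in enumerate(truth):
        for locus in loci:
            if locus.chrom != interval.chrom:
                continue
            dist = max(
                interval.start - locus.position,
                locus.position - (interval.end - 1),
                0,
            )
            if dist <= tol and matrix.present.loc[locus.locus_id].any():
                detected.add(i)
                break
    return detected


def _fmt(x: float | None) -> str:
    return "NA" if x is None else f"{x:.4f}"


def _resolve(path: str, base_dir: Path) -> Path:
    p = Path(path)
    return p if p.is_absolute() else base_dir / p


def _load_bed(path: str | None, base_dir: Path) -> list[GenomicInterval]:
    if not path:
        return []
    return formats_io.read_intervals(_resolve(path, base_dir), "BED")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def validate_config(path: str | Path) -> tuple[RunConfig | None, list[str]]:
    """Load and validate a YAML run config, collecting every error.

    Returns (config, []) on success or (None, errors) listing all
    problems at once rather than failing on the first.
    """
    errors: list[str] = []
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except (OSError, yaml.YAMLError) as exc:
        return None, [f"cannot read config: {exc}"]
    if not isinstance(raw, dict):
        return None, ["config must be a YAML mapping"]

    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    for key in sorted(unknown):
        errors.append(f"unknown config key: {key}")
    for key in ("manifest", "output_dir"):
        if key not in raw:
            errors.append(f"missing required key: {key}")

    base_dir = Path(path).parent
    if "manifest" in raw and not (base_dir / str(raw["manifest"])).exists():
        errors.append(f"manifest not found: {raw['manifest']}")
    for key in (
        "fixed_truth_bed", "reference_mei_bed", "polymorphic_mei_bed",
        "gene_gtf", "segmentation_bed", "pedigree",
    ):
        value = raw.get(key)
        if value and not _resolve(str(value), base_dir).exists():
            errors.append(f"{key} not found: {value}")
    if "window" in raw and (not isinstance(raw["window"], int) or raw["window"] <= 0):
        errors.append("window must be a positive integer")
    if "min_mq" in raw and (
        not isinstance(raw["min_mq"], int) or not 0 <= raw["min_mq"] <= 255
    ):
        errors.append("min_mq must be an integer in [0, 255]")
    if "sensitivity_target" in raw and not (
        0 < float(raw["sensitivity_target"]) < 1
    ):
        errors.append("sensitivity_target must be in (0, 1)")
    if "families" in raw:
        fams = raw["families"]
        if not isinstance(fams, dict) or not fams:
            errors.append("families must be a non-empty mapping name -> cutoff")
        else:
            for name, cutoff in fams.items():
                if not isinstance(cutoff, (int, float)) or cutoff <= 0:
                    errors.append(
                        f"family {name}: bit cutoff must be positive"
                    )
    if errors:
        return None, errors
    return RunConfig(**{k: raw[k] for k in raw if k in known}), []
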