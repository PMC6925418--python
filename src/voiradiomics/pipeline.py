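"""End-to-end study orchestration.

``run_pipeline`` drives: simulate (or load) a cohort -> perturb VOIs ->
extract per-variant feature tables -> ICC robustness vs Baseline -> feature
selection + incremental random-forest modeling per variant -> validation
evaluation with DeLong comparisons vs Baseline -> cross-variant transfer
matrix -> markdown summary.  Every stage writes its artifacts under the run
directory and is skipped on resume when its outputs already exist, so
deleting only downstream outputs reuses upstream artifacts byte-identically.

A single global seed deterministically derives every stage seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import ExtractionGrid, extract_features
from .icc import count_robust, icc_table
from .model import ModelSpec, fit_variant_models, transfer_matrix
from .perturb import STANDARD_PERTURBATIONS, PerturbationSpec, perturb_mask, volume_ratio
from .preprocess import normalize_intensity
from .selection import SelectionConfig
from .synthetic import CohortSpec, SyntheticCase, generate_cohort, write_cohort
from .volume import VARIANTS, VoiMask, load_image, load_mask, save_mask

log = logging.getLogger("voiradiomics")


@dataclass
class RunConfig:
    """Full study configuration; loadable from YAML/JSON."""

    out_dir: str = "voiradiomics_run"
    seed: int = 0
    cohort: CohortSpec | None = None         # synthetic cohort; or
    manifest: str | None = None              # pre-existing cohort manifest CSV
    variants: tuple[str, ...] = tuple(v for v in VARIANTS if v != "baseline")
    grid: ExtractionGrid = field(default_factory=ExtractionGrid)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    model: ModelSpec = field(default_factory=ModelSpec)
    icc_threshold: float = 0.9
    normalize: str | None = None  # "zscore" | "landmark" | None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.cohort is None and self.manifest is None:
            self.cohort = CohortSpec(seed=self.seed)
        # propagate the global seed into stages that kept their defaults
        if self.cohort is not None and self.cohort.seed != self.seed:
            if self.cohort.seed == 0:
                self.cohort = dataclasses.replace(self.cohort, seed=self.seed)
        if self.selection.seed == 0:
            self.selection = dataclasses.replace(self.selection, seed=self.seed + 1)
        if self.model.seed == 0:
            self.model = dataclasses.replace(self.model, seed=self.seed + 2)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "cohort" in kwargs and isinstance(kwargs["cohort"], dict):
            c = dict(kwargs["cohort"])
            for key in ("image_shape", "spacing_mm", "lesion_radius_range_vox"):
                if key in c:
                    c[key] = tuple(c[key])
            kwargs["cohort"] = CohortSpec(**c)
        if "grid" in kwargs and isinstance(kwargs["grid"], dict):
            g = {k: tuple(v) for k, v in kwargs["grid"].items()}
            kwargs["grid"] = ExtractionGrid(**g)
        if "selection" in kwargs and isinstance(kwargs["selection"], dict):
            kwargs["selection"] = SelectionConfig(**kwargs["selection"])
        if "model" in kwargs and isinstance(kwargs["model"], dict):
            kwargs["model"] = ModelSpec(**kwargs["model"])
        if "variants" in kwargs:
            kwargs["variants"] = tuple(kwargs["variants"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj
        return {
            "out_dir": self.out_dir, "seed": self.seed,
            "cohort": enc(self.cohort) if self.cohort else None,
            "manifest": self.manifest, "variants": list(self.variants),
            "grid": enc(self.grid), "selection": enc(self.selection),
            "model": enc(self.model), "icc_threshold": self.icc_threshold,
            "normalize": self.normalize, "log_level": self.log_level,
        }


# ---------------------------------------------------------------------------
# manifest I/O and validation
# ---------------------------------------------------------------------------

def load_cohort_from_manifest(manifest: str | Path) -> list[SyntheticCase]:
    manifest = Path(manifest)
    df = pd.read_csv(manifest)
    base = manifest.parent
    cases = []
    for _, row in df.iterrows():
        image = load_image(base / row["image"])
        mask = load_mask(base / row["mask"])
        cases.append(SyntheticCase(
            subject_id=str(row["subject_id"]), class_label=int(row["label"]),
            image=image, mask=mask, split=str(row["split"]),
        ))
    return cases


def validate_inputs(manifest: str | Path) -> list[dict]:
    """Diagnostics on a cohort manifest: shape/spacing agreement, nonempty
    masks, binary labels, known splits.  Returns machine-readable issues;
    ``severity == "fatal"`` entries must stop the pipeline."""
    manifest = Path(manifest)
    issues: list[dict] = []
    if not manifest.exists():
        return [{"severity": "fatal", "subject": None, "issue": f"manifest {manifest} missing"}]
    df = pd.read_csv(manifest)
    base = manifest.parent
    for _, row in df.iterrows():
        sid = str(row["subject_id"])
        try:
            image = load_image(base / row["image"])
            mask = load_mask(base / row["mask"])
        except Exception as exc:
            issues.append({"severity": "fatal", "subject": sid, "issue": f"unreadable: {exc}"})
            continue
        if mask.shape != image.shape:
            issues.append({"severity": "fatal", "subject": sid,
                           "issue": f"mask shape {mask.shape} != image shape {image.shape}"})
        elif not np.allclose(mask.spacing_mm, image.spacing_mm):
            issues.append({"severity": "fatal", "subject": sid, "issue": "spacing mismatch"})
        if mask.is_empty:
            issues.append({"severity": "fatal", "subject": sid, "issue": "empty VOI"})
        if int(row["label"]) not in (0, 1):
            issues.append({"severity": "fatal", "subject": sid,
                           "issue": f"label {row['label']} not in {{0, 1}}"})
        if str(row["split"]) not in ("training", "validation"):
            issues.append({"severity": "fatal", "subject": sid,
                           "issue": f"unknown split {row['split']!r}"})
    return issues


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_cohort(config: RunConfig, run_dir: Path) -> Path:
    if config.manifest is not None:
        return Path(config.manifest)
    manifest = run_dir / "cohort" / "manifest.csv"
    if manifest.exists():
        log.info("cohort: reusing %s", manifest)
        return manifest
    log.info("cohort: simulating %d cases", 2 * config.cohort.n_per_class)
    cases = generate_cohort(config.cohort)
    return write_cohort(cases, run_dir / "cohort")


def _stage_perturb(config: RunConfig, run_dir: Path, cases) -> dict[str, dict[str, VoiMask]]:
    mask_dir = run_dir / "masks"
    mask_dir.mkdir(parents=True, exist_ok=True)
    variant_masks: dict[str, dict[str, VoiMask]] = {"baseline": {c.subject_id: c.mask for c in cases}}
    ratios: dict[str, list[float]] = {}
    for tag in config.variants:
        op, radius = STANDARD_PERTURBATIONS[tag]
        spec = PerturbationSpec(operation=op, radius_px=radius)
        variant_masks[tag] = {}
        ratios[tag] = []
        for case in cases:
            path = mask_dir / f"{case.subject_id}_mask_{tag}.nii.gz"
            if path.exists():
                mask = load_mask(path, variant=tag)
            else:
                mask = perturb_mask(case.mask, spec)
                if mask.empty_after_perturbation:
                    raise RuntimeError(f"perturb: variant {tag} emptied subject {case.subject_id}")
                save_mask(mask, path)
            variant_masks[tag][case.subject_id] = mask
            ratios[tag].append(volume_ratio(mask, case.mask))
    ratio_path = run_dir / "masks" / "volume_ratios.csv"
    if not ratio_path.exists():
        rows = [{"variant": tag,
                 "mean_ratio": float(np.mean(r)),
                 "ci95_low": float(np.percentile(r, 2.5)),
                 "ci95_high": float(np.percentile(r, 97.5))}
                for tag, r in ratios.items()]
        pd.DataFrame(rows).to_csv(ratio_path, index=False)
    return variant_masks


def _stage_extract(config: RunConfig, run_dir: Path, cases, variant_masks) -> dict[str, pd.DataFrame]:
    feat_dir = run_dir / "features"
    feat_dir.mkdir(parents=True, exist_ok=True)
    tables = {}
    for tag, masks in variant_masks.items():
        path = feat_dir / f"features_{tag}.csv"
        if path.exists():
            log.info("extract: reusing %s", path)
            tables[tag] = pd.read_csv(path, index_col="subject_id")
            continue
        log.info("extract: variant %s (%d cases)", tag, len(cases))
        rows, meta = {}, {}
        for case in cases:
            image = case.image
            if config.normalize:
                image = normalize_intensity(image, config.normalize)
            try:
                rows[case.subject_id] = extract_features(image, masks[case.subject_id], config.grid)
            except ValueError as exc:
                raise RuntimeError(f"extract: variant {tag}, subject {case.subject_id}: {exc}") from exc
            meta[case.subject_id] = (case.class_label, case.split)
        table = pd.DataFrame(rows).T
        table["label"] = [meta[s][0] for s in table.index]
        table["split"] = [meta[s][1] for s in table.index]
        table.index.name = "subject_id"
        table.to_csv(path)
        tables[tag] = table
    return tables


def _stage_icc(config: RunConfig, run_dir: Path, tables) -> pd.DataFrame:
    icc_dir = run_dir / "icc"
    icc_dir.mkdir(parents=True, exist_ok=True)
    icc_path = icc_dir / "icc.csv"
    if icc_path.exists():
        results = pd.read_csv(icc_path)
    else:
        variant_tables = {t: tables[t] for t in tables if t != "baseline"}
        results = icc_table(tables["baseline"], variant_tables)
        results.to_csv(icc_path, index=False)
    counts_path = icc_dir / "robust_counts.json"
    if not counts_path.exists():
        counts = count_robust(results, threshold=config.icc_threshold)
        counts_path.write_text(counts.to_json(orient="records", indent=2))
    return results


def _stage_model(config: RunConfig, run_dir: Path, tables):
    sel_dir = run_dir / "selection"
    model_dir = run_dir / "models"
    sel_dir.mkdir(parents=True, exist_ok=True)
    model_dir.mkdir(parents=True, exist_ok=True)

    results = fit_variant_models(tables, selection=config.selection, spec=config.model)
    for tag, res in results.items():
        path = sel_dir / f"selection_{tag}.json"
        if not path.exists():
            res.selection_result.to_json(path)

    eval_path = model_dir / "evaluation.csv"
    rows = []
    val_tables = {t: tab[tab["split"] == "validation"] for t, tab in tables.items()}
    base = results["baseline"]
    for tag, res in results.items():
        row = res.evaluate(val_tables[tag])
        if tag == "baseline":
            p = np.nan
        else:
            p = res.compare(base, val_tables[tag], val_tables["baseline"])["p"]
        overlap = res.selection_result.overlap_with(base.selection_result)
        rows.append({
            "variant": tag, "k": row.k, "auc": row.auc,
            "ci_low": row.ci_low, "ci_high": row.ci_high,
            "p_vs_baseline": p, "sensitivity": row.sensitivity,
            "specificity": row.specificity, "accuracy": row.accuracy,
            "top20_overlap_with_baseline": overlap,
        })
    evaluation = pd.DataFrame(rows)
    if not eval_path.exists():
        evaluation.to_csv(eval_path, index=False)

    transfer_path = model_dir / "transfer_matrix.csv"
    transfer = transfer_matrix(results, val_tables)
    if not transfer_path.exists():
        transfer.to_csv(transfer_path)
    return results, evaluation, transfer


def _stage_report(config: RunConfig, run_dir: Path, evaluation, transfer, icc_results) -> Path:
    report = run_dir / "report" / "summary.md"
    report.parent.mkdir(parents=True, exist_ok=True)
    counts = count_robust(icc_results, threshold=config.icc_threshold)
    lines = [
        "# VOI delineation-robustness study",
        "",
        f"package voiradiomics {__version__}, seed {config.seed}",
        "",
        "## Robust features (ICC >= %.2f)" % config.icc_threshold,
        "",
        "```",
        counts.to_string(index=False),
        "```",
        "",
        "## Validation performance per delineation variant",
        "",
        "```",
        evaluation.round(3).to_string(index=False),
        "```",
        "",
        "## Cross-delineation transfer AUCs (rows = model, cols = validation data)",
        "",
        "```",
        transfer.astype(float).round(3).to_string(),
        "```",
        "",
    ]
    report.write_text("\n".join(lines))
    (run_dir / "report" / "provenance.json").write_text(
        json.dumps({"config": config.to_dict(), "version": __version__}, indent=2)
    )
    return report


def run_pipeline(config: RunConfig) -> Path:
    """Run the full study; returns the run directory."""
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    fh = logging.FileHandler(run_dir / "run.log")
    log.addHandler(fh)
    try:
        manifest = _stage_cohort(config, run_dir)
        issues = validate_inputs(manifest)
        fatal = [i for i in issues if i["severity"] == "fatal"]
        if fatal:
            raise RuntimeError(f"input validation failed: {fatal[:3]}")
        cases = load_cohort_from_manifest(manifest)
        variant_masks = _stage_perturb(config, run_dir, cases)
        tables = _stage_extract(config, run_dir, cases, variant_masks)
        icc_results = _stage_icc(config, run_dir, tables)
        _, evaluation, transfer = _stage_model(config, run_dir, tables)
        _stage_report(config, run_dir, evaluation, transfer, icc_results)
    finally:
        log.removeHandler(fh)
        fh.close()
    return run_dir
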