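"""End-to-end orchestration: simulate/load → preprocess → segment → score →
recurrence (→ optional cross-species), with validated inputs and a run
manifest.

Configuration is a single YAML file with nested sections mirroring the
parameter dataclasses; all tabular outputs are TSV, segments are SEG.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import fgmp as fgmp_mod
from .cohort import ExpressionCohort
from .genome import normalize_chromosome, read_cytoband_file
from .instability import dgi_table
from .preprocess import PreprocessParams, preprocess
from .recurrence import recurrence_test, segments_to_cytobands, specificity_scan
from .segmentation import PCFParams, export_seg, segment_cohort

log = logging.getLogger("ekaryo")

__all__ = ["RunConfig", "validate_inputs", "run_pipeline"]


@dataclass
class RunConfig:
    expression_path: str
    cytoband_path: str
    output_dir: str
    samples_path: str | None = None
    components_path: str | None = None
    components_sidecar: str | None = None
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    pcf: PCFParams = field(default_factory=PCFParams)
    autocorr_lag: int = 10
    prevalence_cutoff: float = 0.10
    alpha: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        pp = PreprocessParams(**raw.pop("preprocess", {}))
        pcf = PCFParams(**raw.pop("pcf", {}))
        return cls(preprocess=pp, pcf=pcf, **raw)


def _sha1(path) -> str:
    h = hashlib.sha1()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_inputs(config: RunConfig) -> list[str]:
    """Pre-flight checks; returns a list of violations (empty = valid)."""
    violations = []
    for name in ("expression_path", "cytoband_path", "samples_path",
                 "components_path"):
        p = getattr(config, name)
        if p is not None and not Path(p).exists():
            violations.append(f"{name}: file not found: {p}")
    if violations:
        return violations
    try:
        cohort = ExpressionCohort.from_tsv(config.expression_path,
                                           config.samples_path)
    except Exception as exc:  # malformed header
        return [f"expression_path: {exc}"]
    # sortedness in genome order
    from .genome import chromosome_sort_key
    keys = [(chromosome_sort_key(c), p) for c, p in
            zip(cohort.genes["chromosome"], cohort.genes["position"])]
    for i in range(1, len(keys)):
        if keys[i] < keys[i - 1]:
            violations.append(
                f"expression_path: genes not in genome order at row {i} "
                f"(gene {cohort.genes['gene_id'].iloc[i]})")
            break
    try:
        bands = read_cytoband_file(config.cytoband_path)
    except Exception as exc:
        violations.append(f"cytoband_path: {exc}")
        return violations
    expr_chroms = {normalize_chromosome(c) for c in cohort.genes["chromosome"]}
    band_chroms = set(bands["chromosome"])
    missing = expr_chroms - band_chroms
    if missing:
        violations.append(
            f"chromosome naming mismatch: expression chromosomes "
            f"{sorted(missing)} absent from cytoband file")
    return violations


def run_pipeline(config: RunConfig) -> dict:
    """Run the full chain and return the manifest (also written to disk).

    Outputs under ``output_dir``: comparative_matrix.tsv, segments.seg,
    dgi_table.tsv, band_matrix.tsv, recurrence.tsv, specificity.tsv (when
    >1 model) and manifest.json.  Deterministic for identical config+seed.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    t0 = time.time()
    violations = validate_inputs(config)
    if violations:
        raise ValueError("invalid inputs:\n" + "\n".join(violations))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": config.seed,
        "inputs": {p: _sha1(getattr(config, p))
                   for p in ("expression_path", "cytoband_path", "samples_path")
                   if getattr(config, p)},
        "parameters": {"preprocess": vars(config.preprocess),
                       "pcf": {k: v for k, v in vars(config.pcf).items()},
                       "autocorr_lag": config.autocorr_lag,
                       "prevalence_cutoff": config.prevalence_cutoff,
                       "alpha": config.alpha},
        "stages": {}, "outputs": [], "status": "running",
    }

    def _fail(stage, exc):
        manifest["status"] = f"failed:{stage}"
        manifest["error"] = str(exc)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise

    try:
        cohort = ExpressionCohort.from_tsv(config.expression_path,
                                           config.samples_path)
        manifest["stages"]["load"] = {"genes": cohort.n_genes,
                                      "samples": cohort.n_samples}
        comparative = preprocess(cohort, config.preprocess)
        manifest["stages"]["preprocess"] = {"genes": comparative.n_genes}
        if config.components_path:
            comps = fgmp_mod.TranscriptionalComponents.load(
                config.components_path, config.components_sidecar)
            comparative = fgmp_mod.correct_profiles(comparative, comps)
            manifest["stages"]["fgmp"] = {"k": comps.k,
                                          "genes": comparative.n_genes}
        comp_path = outdir / "comparative_matrix.tsv"
        comparative.to_tsv(comp_path)
        manifest["outputs"].append(str(comp_path))
    except Exception as exc:
        _fail("preprocess", exc)

    try:
        segset = segment_cohort(comparative, config.pcf)
        seg_path = outdir / "segments.seg"
        export_seg(segset, seg_path)
        manifest["outputs"].append(str(seg_path))
        manifest["stages"]["segmentation"] = {
            "segments": len(segset.segments),
            "called": int((segset.segments["call"] != 0).sum())}
    except Exception as exc:
        _fail("segmentation", exc)

    try:
        autocorr = fgmp_mod.autocorrelation_table(
            comparative, fgmp_mod.AutocorrelationParams(lag=config.autocorr_lag))
        dgi = dgi_table(segset, autocorr=autocorr)
        labels = comparative.samples.set_index("sample_id")["model_label"]
        dgi["model_label"] = dgi["sample"].map(labels).values
        dgi_path = outdir / "dgi_table.tsv"
        dgi.to_csv(dgi_path, sep="\t", index=False)
        manifest["outputs"].append(str(dgi_path))
        manifest["stages"]["dgi"] = {"samples": len(dgi)}
    except Exception as exc:
        _fail("dgi", exc)

    try:
        bands = read_cytoband_file(config.cytoband_path)
        matrix = segments_to_cytobands(segset, bands, labels)
        band_path = outdir / "band_matrix.tsv"
        matrix.to_tsv(band_path)
        manifest["outputs"].append(str(band_path))
        rec_tables = []
        for model in sorted(matrix.model_labels.unique()):
            sub = matrix.restrict_model(model)
            for direction in ("gain", "loss"):
                t = recurrence_test(sub, direction,
                                    prevalence_cutoff=config.prevalence_cutoff,
                                    alpha=config.alpha)
                t.insert(0, "model", model)
                rec_tables.append(t)
        rec = pd.concat(rec_tables, ignore_index=True)
        rec_path = outdir / "recurrence.tsv"
        rec.to_csv(rec_path, sep="\t", index=False)
        manifest["outputs"].append(str(rec_path))
        manifest["stages"]["recurrence"] = {
            "recurrent": int(rec["recurrent"].sum())}
        if matrix.model_labels.nunique() > 1:
            spec = specificity_scan(matrix, alpha=config.alpha)
            spec_path = outdir / "specificity.tsv"
            spec.drop(columns=["models", "event_counts", "sizes"],
                      errors="ignore").to_csv(spec_path, sep="\t", index=False)
            manifest["outputs"].append(str(spec_path))
            manifest["stages"]["specificity"] = {
                "tested": int(len(spec)),
                "specific": int(spec["model_specific"].sum()) if len(spec) else 0}
    except Exception as exc:
        _fail("recurrence", exc)

    manifest["status"] = "ok"
    manifest["elapsed_s"] = round(time.time() - t0, 2)
    man_path = outdir / "manifest.json"
    tmp = man_path.with_suffix(".json.tmp")
    tmp.write_text(json.dumps(manifest, indent=1))
    tmp.replace(man_path)
    manifest["outputs"].append(str(man_path))
    return manifest
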