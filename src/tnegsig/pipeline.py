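"""Configuration-driven orchestration of the full analysis.

Stage order: simulate -> prep -> discover -> index -> compare.  Every
stage writes its artifacts (TSV/JSON only; figures are emitted as
coordinate data) before the next stage starts, and the run closes with
a :class:`RunManifest` recording the config hash, per-artifact SHA-256
checksums and wall-clock per stage.

Determinism: a single global seed is expanded into per-stage sub-seeds
by stable hashing of the stage name, so adding a stage never reshuffles
the randomness of the others.  Re-running an identical config + seed
reproduces identical artifact checksums (audit logs carry timestamps
and are excluded from the checksum set).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .bundle import CohortBundle
from .compare import (
    compare_prognosis,
    correlate_indices,
    signature_indices,
)
from .discovery import MCCVConfig, discover
from .index import (
    GeneSignature,
    compute_index,
    dichotomize,
    load_packaged_signature,
    optimize_cutpoint,
    stepwise_addition,
)
from .prep import assign_her2_status, mean_center_within_source, merge_cohorts
from .simulate import ERBB2_FEATURE, SimulationParams, simulate_cohort
from .survival import km_estimate

log = logging.getLogger(__name__)

STAGES = ("simulate", "prep", "discover", "index", "compare")


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage sub-seed below 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Declarative run description (YAML/JSON serialisable)."""

    seed: int = 0
    out_dir: str = "tnegsig_run"
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    simulate: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)  # expression/clinical/probe_map
    prep: dict = field(default_factory=dict)
    discover: dict = field(default_factory=dict)
    index: dict = field(default_factory=dict)
    compare: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "out_dir": self.out_dir,
            "stages": list(self.stages),
            "simulate": dict(self.simulate),
            "paths": dict(self.paths),
            "prep": dict(self.prep),
            "discover": dict(self.discover),
            "index": dict(self.index),
            "compare": dict(self.compare),
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data or {})

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location and
        logging verbosity do not affect results and are excluded)."""
        payload = self.to_dict()
        payload.pop("out_dir")
        payload.pop("log_level")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    package_version: str
    seed: int
    checksums: dict[str, str] = field(default_factory=dict)
    wall_clock: dict[str, float] = field(default_factory=dict)

    def fingerprint(self) -> str:
        """Hash of the deterministic portion (config + artifact checksums)."""
        payload = json.dumps(
            {"config": self.config_hash, "checksums": self.checksums},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "package_version": self.package_version,
            "seed": self.seed,
            "checksums": dict(self.checksums),
            "wall_clock": dict(self.wall_clock),
            "fingerprint": self.fingerprint(),
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _checksum_outputs(manifest: RunManifest, outdir: Path) -> None:
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "manifest.json" and "transforms" not in p.name:
            manifest.checksums[str(p.relative_to(outdir))] = _sha256(p)


def run(config: PipelineConfig) -> RunManifest:
    """Execute the configured stages in order; see module docstring."""
    from importlib.metadata import version

    try:
        pkg_version = version("tnegsig")
    except Exception:
        pkg_version = "unknown"

    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config.config_hash(),
        package_version=pkg_version,
        seed=config.seed,
    )

    bundle: CohortBundle | None = None
    truth = None
    merged: CohortBundle | None = None
    signature: GeneSignature | None = None

    for stage in config.stages:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        t0 = time.perf_counter()
        try:
            if stage == "simulate":
                params = SimulationParams(
                    **{**config.simulate, "seed": stage_seed(config.seed, "simulate")}
                )
                bundle, truth = simulate_cohort(params)
                tio.write_bundle(bundle, outdir, prefix="cohort")
                tio.write_ground_truth(truth, outdir / "ground_truth.json")

            elif stage == "prep":
                if bundle is None:
                    bundle = tio.read_bundle(
                        config.paths["expression"],
                        config.paths["clinical"],
                        config.paths.get("probe_map"),
                    )
                erbb2 = config.prep.get("erbb2_feature_id", ERBB2_FEATURE)
                threshold = config.prep.get("her2_threshold", 0.0)
                bundle = assign_her2_status(bundle, erbb2, threshold=threshold)
                strategy = config.prep.get("merge_strategy", "dwd_lite")
                per_source = [
                    mean_center_within_source(
                        bundle.subset_samples(bundle.source_mask(s))
                    )
                    for s in bundle.sources
                ]
                merged = merge_cohorts(per_source, strategy=strategy)
                tio.write_bundle(merged, outdir, prefix="merged")

            elif stage == "discover":
                if bundle is None or "tneg" not in bundle.clinical.columns:
                    raise RuntimeError("discover requires the prep stage first")
                layout = config.discover.get(
                    "layout",
                    {
                        "discovery": bundle.sources[:-1],
                        "holdout": bundle.sources[-1:],
                    },
                )
                mccv_kwargs = dict(config.discover.get("mccv", {}))
                mccv_kwargs["seed"] = stage_seed(config.seed, "discover")
                result = discover(
                    bundle,
                    layout,
                    mccv_config=MCCVConfig(**mccv_kwargs),
                    pam_top_k=config.discover.get("pam_top_k", 300),
                    variance_min_fraction=config.discover.get(
                        "variance_min_fraction", 0.10
                    ),
                    variance_log2_fold=config.discover.get("variance_log2_fold", 1.0),
                    combine=config.discover.get("combine", "union"),
                )
                signature = result.combined_signature
                result.hrneg_records.to_csv(outdir / "candidates_hrneg.tsv", sep="\t")
                result.tneg_records.to_csv(outdir / "candidates_tneg.tsv", sep="\t")
                signature.to_tsv(outdir / "discovered_signature.tsv")

            elif stage == "index":
                if merged is None:
                    raise RuntimeError("index requires the prep stage first")
                sig = _resolve_signature(config.index, signature)
                idx = compute_index(merged, sig)
                idx.scores.rename("index").to_frame().to_csv(
                    outdir / "index_scores.tsv", sep="\t", index_label="sample_id"
                )
                times, events = merged.times, merged.events
                summary = {}
                for pct in config.index.get("percentiles", (50, 75)):
                    groups, cp = dichotomize(idx, times, events, percentile=pct)
                    km = km_estimate(times, events, groups.to_numpy())
                    _write_km(km, outdir / f"km_pct{int(pct)}.json")
                    summary[f"pct{int(pct)}"] = _cutpoint_dict(cp)
                opt = optimize_cutpoint(
                    idx,
                    times,
                    events,
                    lower_pct=config.index.get("lower_pct", 20.0),
                    upper_pct=config.index.get("upper_pct", 80.0),
                )
                opt.grid.to_csv(outdir / "cutpoint_grid.tsv", sep="\t", index=False)
                summary["optimized"] = _cutpoint_dict(opt)
                summary["optimized"]["exploratory"] = True
                if config.index.get("stepwise", True) and signature is not None:
                    sw = stepwise_addition(sig.members, merged, times, events)
                    sw.steps.to_csv(outdir / "stepwise_addition.tsv", sep="\t", index=False)
                    summary["stepwise_best_subset"] = sw.best_subset
                (outdir / "index_summary.json").write_text(
                    json.dumps(summary, indent=2, default=tio.json_default)
                )

            elif stage == "compare":
                if merged is None:
                    raise RuntimeError("compare requires the prep stage first")
                library = _resolve_library(config.compare, signature, merged, config.seed)
                report = compare_prognosis(merged, library)
                report.to_csv(outdir / "comparison.tsv", sep="\t")
                idx_frame = signature_indices(merged, library)
                R, P = correlate_indices(idx_frame)
                (outdir / "correlations.json").write_text(
                    json.dumps(
                        {"r": R.to_dict(), "p": P.to_dict()},
                        indent=2,
                        default=tio.json_default,
                    )
                )
        except Exception as err:
            record = {"stage": stage, "error": type(err).__name__, "message": str(err)}
            (outdir / "error.json").write_text(json.dumps(record, indent=2))
            raise RuntimeError(f"stage {stage!r} failed: {err}") from err
        manifest.wall_clock[stage] = time.perf_counter() - t0

    _checksum_outputs(manifest, outdir)
    (outdir / "manifest.json").write_text(json.dumps(manifest.to_dict(), indent=2))
    return manifest


def _cutpoint_dict(cp) -> dict:
    return {
        "cut_value": cp.cut_value,
        "percentile": cp.percentile,
        "n_high": cp.n_high,
        "n_low": cp.n_low,
        "logrank_chi2": cp.logrank_chi2,
        "logrank_p": cp.logrank_p,
        "hr_high_vs_low": cp.hr_high_vs_low,
        "hr_ci95": list(cp.hr_ci95),
        "cox_p": cp.cox_p,
    }


def _write_km(km, path: Path) -> None:
    payload = {
        "curves": {
            str(g): df.to_dict(orient="list") for g, df in km.curves.items()
        },
        "logrank_chi2": km.logrank_chi2,
        "logrank_p": km.logrank_p,
    }
    path.write_text(json.dumps(payload, indent=2, default=tio.json_default))


def _resolve_signature(index_cfg: dict, discovered: GeneSignature | None) -> GeneSignature:
    if "signature_file" in index_cfg:
        return GeneSignature.from_tsv(index_cfg["signature_file"])
    if "packaged_signature" in index_cfg:
        return load_packaged_signature(index_cfg["packaged_signature"])
    if discovered is not None:
        return discovered
    raise RuntimeError("index stage needs a discovered or configured signature")


def _resolve_library(
    compare_cfg: dict,
    discovered: GeneSignature | None,
    merged: CohortBundle,
    seed: int,
) -> dict[str, GeneSignature]:
    library: dict[str, GeneSignature] = {}
    sig_dir = compare_cfg.get("signature_dir")
    if sig_dir:
        for path in sorted(Path(sig_dir).glob("*.tsv")):
            library[path.stem] = GeneSignature.from_tsv(path, name=path.stem)
    if discovered is not None:
        library.setdefault("discovered", discovered)
    if compare_cfg.get("add_null_comparator", True):
        rng = np.random.default_rng(stage_seed(seed, "compare"))
        pool = [g for g in merged.expression.index]
        pick = rng.choice(len(pool), size=min(20, len(pool)), replace=False)
        library.setdefault(
            "random_20",
            GeneSignature(
                name="random_20",
                members={str(pool[i]): -1 for i in pick},
                provenance="synthetic null comparator (random genes)",
            ),
        )
    if len(library) < 2:
        raise RuntimeError("compare stage needs at least two signatures")
    return library


def report(out_dir) -> str:
    """Assemble a human-readable summary from stage outputs.

    Missing stage outputs are flagged as gaps rather than errors, so a
    partial run still yields a partial report.
    """
    outdir = Path(out_dir)
    lines = ["# tnegsig run report", ""]

    cand = outdir / "candidates_hrneg.tsv"
    if cand.exists():
        df = pd.read_csv(cand, sep="\t", index_col=0)
        final = df[df["final_selected"] == True]  # noqa: E712
        lines.append("## Candidate table (discovery, final candidates)")
        lines.append("")
        cols = ["gene_symbol", "uni_coef", "uni_p", "multi_coef", "multi_p"]
        lines.append(final[cols].to_string())
    else:
        lines.append("## Candidate table: MISSING (discover stage not run)")
    lines.append("")

    summary = outdir / "index_summary.json"
    if summary.exists():
        lines.append("## Index dichotomisation summary")
        lines.append(summary.read_text())
    else:
        lines.append("## Index summary: MISSING (index stage not run)")
    lines.append("")

    comp = outdir / "comparison.tsv"
    if comp.exists():
        lines.append("## Signature comparison (median cut)")
        lines.append(pd.read_csv(comp, sep="\t").to_string(index=False))
    else:
        lines.append("## Signature comparison: MISSING (compare stage not run)")
    lines.append("")

    corr = outdir / "correlations.json"
    if corr.exists():
        lines.append("## Index correlation matrix (Pearson R)")
        R = pd.DataFrame(json.loads(corr.read_text())["r"])
        lines.append(R.round(3).to_string())
    lines.append("")

    text = "\n".join(lines)
    (outdir / "report.md").write_text(text)
    return text
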