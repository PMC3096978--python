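"""Plain-text I/O: TSV expression/clinical tables, JSON sidecars.

Dialect: tab-separated, expression rows are features with a header row
of sample ids; clinical tables are one row per sample.  Ground truth
and audit logs serialise to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bundle import CohortBundle
from .simulate import GroundTruth


def write_expression(bundle: CohortBundle, path) -> None:
    bundle.expression.to_csv(path, sep="\t", index_label="feature_id")


def write_clinical(bundle: CohortBundle, path) -> None:
    bundle.clinical.to_csv(path, sep="\t", index_label="sample_id")


def read_bundle(expression_path, clinical_path, probe_map_path=None) -> CohortBundle:
    expr = pd.read_csv(expression_path, sep="\t", index_col=0)
    clin = pd.read_csv(clinical_path, sep="\t", index_col=0)
    fmap = None
    if probe_map_path is not None:
        fm = pd.read_csv(probe_map_path, sep="\t")
        fmap = pd.Series(fm.iloc[:, 1].to_numpy(), index=fm.iloc[:, 0])
    return CohortBundle(expression=expr, clinical=clin, feature_map=fmap)


def write_bundle(bundle: CohortBundle, outdir, prefix: str = "cohort") -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / f"{prefix}_expression.tsv",
        "clinical": outdir / f"{prefix}_clinical.tsv",
    }
    write_expression(bundle, paths["expression"])
    write_clinical(bundle, paths["clinical"])
    if bundle.transforms:
        audit = outdir / f"{prefix}_transforms.json"
        audit.write_text(
            json.dumps([t.to_dict() for t in bundle.transforms], indent=2)
        )
        paths["transforms"] = audit
    return {k: str(v) for k, v in paths.items()}


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "prognostic_gene_ids": truth.prognostic_gene_ids,
        "true_betas": truth.true_betas.to_dict(),
        "per_sample_linear_predictor": truth.per_sample_linear_predictor.to_dict(),
        "true_event_times": truth.true_event_times.to_dict(),
        "censoring_times": truth.censoring_times.to_dict(),
        "her2_positive": {k: bool(v) for k, v in truth.her2_positive.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        prognostic_gene_ids=payload["prognostic_gene_ids"],
        true_betas=pd.Series(payload["true_betas"], dtype=float),
        per_sample_linear_predictor=pd.Series(
            payload["per_sample_linear_predictor"], dtype=float
        ),
        true_event_times=pd.Series(payload["true_event_times"], dtype=float),
        censoring_times=pd.Series(payload["censoring_times"], dtype=float),
        her2_positive=pd.Series(payload["her2_positive"], dtype=bool),
    )


def json_default(obj):
    """JSON encoder hook for NumPy scalars and arrays."""
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
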