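"""Per-source expression transforms and multi-source merging.

All operations consume and produce :class:`~tnegsig.bundle.CohortBundle`
objects and append a :class:`~tnegsig.bundle.TransformRecord` so a merged
cohort carries a full audit trail of what was done per source.

Conventions (documented design choices):

* Z-transform uses the sample standard deviation (n-1 denominator);
  zero-variance features are flagged and left centred at 0.
* HER2 status is called positive when the per-source mean-centred log2
  ERBB2 value exceeds 0 (the cut is configurable).  The triple-negative
  flag is ER-negative AND PR-not-positive AND HER2-negative: a missing
  PR annotation does not block the call.
* ``merge_cohorts`` offers ``"center"`` (per-source mean-centring of
  the intersected features, then concatenation) and ``"dwd_lite"``
  (translation of each batch along the direction separating it from a
  reference batch so batch centroids coincide).  Both are pure
  per-source translations, so all within-source statistics -- pairwise
  distances, variances, correlations -- are preserved exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bundle import CohortBundle, TransformRecord


def _per_source_groups(bundle: CohortBundle) -> dict[str, list]:
    groups: dict[str, list] = {}
    src = bundle.clinical["source"]
    for s in bundle.expression.columns:
        groups.setdefault(src[s], []).append(s)
    return groups


def mean_center_within_source(bundle: CohortBundle) -> CohortBundle:
    """Subtract the per-(source, feature) mean; idempotent."""
    expr = bundle.expression.copy()
    params: dict[str, dict] = {}
    for source, samples in _per_source_groups(bundle).items():
        if len(samples) < 2:
            raise ValueError(
                f"source {source!r} has fewer than 2 samples; cannot centre"
            )
        mu = expr[samples].mean(axis=1)
        expr[samples] = expr[samples].sub(mu, axis=0)
        params[source] = {"n": len(samples)}
    rec = TransformRecord("mean_center_within_source", {"sources": params})
    return bundle.with_expression(expr, rec)


def z_transform_within_source(bundle: CohortBundle) -> CohortBundle:
    """Standardise each feature to mean 0, SD 1 within every source.

    Sample SD (n-1).  Features with zero variance in a source are not
    divided; they stay centred at 0 and are recorded in the audit entry.
    """
    expr = bundle.expression.copy()
    flagged: dict[str, list[str]] = {}
    for source, samples in _per_source_groups(bundle).items():
        if len(samples) < 2:
            raise ValueError(
                f"source {source!r} has fewer than 2 samples; cannot standardise"
            )
        block = expr[samples]
        mu = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        zero = sd <= 0
        sd_safe = sd.mask(zero, 1.0)
        expr[samples] = block.sub(mu, axis=0).div(sd_safe, axis=0)
        if zero.any():
            flagged[source] = [str(f) for f in expr.index[zero]]
    rec = TransformRecord(
        "z_transform_within_source", {"zero_variance_features": flagged}
    )
    return bundle.with_expression(expr, rec)


def variance_filter(
    bundle: CohortBundle,
    min_fraction: float = 0.10,
    log2_fold: float = 1.0,
) -> tuple[CohortBundle, list]:
    """Minimum-variation filter on log2-scale expression.

    A feature is kept iff at least ``min_fraction`` of the samples
    deviate from the feature mean by strictly more than ``log2_fold``
    log2 units (twofold at the default 1.0).
    """
    if bundle.n_features == 0 or bundle.n_samples == 0:
        raise ValueError("empty expression matrix")
    X = bundle.expression.to_numpy(dtype=float)
    dev = np.abs(X - X.mean(axis=1, keepdims=True))
    frac = (dev > log2_fold).mean(axis=1)
    keep = frac >= min_fraction
    kept_ids = list(bundle.expression.index[keep])
    rec = TransformRecord(
        "variance_filter",
        {
            "min_fraction": min_fraction,
            "log2_fold": log2_fold,
            "n_in": int(bundle.n_features),
            "n_kept": len(kept_ids),
        },
    )
    out = bundle.with_expression(bundle.expression.loc[kept_ids].copy(), rec)
    return out, kept_ids


def collapse_probes(bundle: CohortBundle) -> CohortBundle:
    """Collapse probe-level rows to gene symbols by unweighted averaging.

    Probes without a symbol in ``feature_map`` are dropped; their count
    is recorded in the audit entry.
    """
    if bundle.feature_map is None or len(bundle.feature_map) == 0:
        raise ValueError("collapse_probes requires a non-empty feature_map")
    fmap = bundle.feature_map
    probes = bundle.expression.index
    mapped = probes.intersection(fmap.index)
    mapped_set = set(mapped)
    dropped = [str(pr) for pr in probes if pr not in mapped_set]
    expr = bundle.expression.loc[mapped]
    symbols = fmap.loc[mapped]
    collapsed = expr.groupby(symbols.to_numpy()).mean()
    collapsed.index.name = bundle.expression.index.name
    rec = TransformRecord(
        "collapse_probes",
        {
            "n_probes": int(len(probes)),
            "n_genes": int(collapsed.shape[0]),
            "n_unmapped_dropped": len(dropped),
            "unmapped": dropped[:50],
        },
    )
    out = bundle.with_expression(collapsed, rec)
    out.feature_map = None
    return out


def assign_her2_status(
    bundle: CohortBundle,
    erbb2_feature_id: str,
    threshold: float = 0.0,
) -> CohortBundle:
    """Call HER2 status from per-source mean-centred log2 ERBB2 levels.

    ``her2_status`` is "pos" iff the centred value is strictly greater
    than ``threshold``; the boundary value is called negative.  Adds a
    boolean ``tneg`` column: ER negative AND PR negative-or-unknown AND
    HER2 negative.
    """
    if erbb2_feature_id not in bundle.expression.index:
        raise ValueError(f"ERBB2 feature {erbb2_feature_id!r} not in expression")
    clinical = bundle.clinical.copy()
    erbb2 = bundle.expression.loc[erbb2_feature_id]
    status = pd.Series("neg", index=clinical.index, dtype=object)
    for source, samples in _per_source_groups(bundle).items():
        centred = erbb2[samples] - erbb2[samples].mean()
        status.loc[samples] = np.where(centred > threshold, "pos", "neg")
    clinical["her2_status"] = status
    er = clinical.get("er_status", pd.Series("unknown", index=clinical.index))
    pr = clinical.get("pr_status", pd.Series("unknown", index=clinical.index))
    clinical["tneg"] = (
        (er == "neg") & (pr != "pos") & (clinical["her2_status"] == "neg")
    )
    rec = TransformRecord(
        "assign_her2_status",
        {
            "erbb2_feature_id": str(erbb2_feature_id),
            "threshold": threshold,
            "n_her2_pos": int((clinical["her2_status"] == "pos").sum()),
            "n_tneg": int(clinical["tneg"].sum()),
        },
    )
    return bundle.with_clinical(clinical, rec)


def _separating_direction(
    ref: np.ndarray, other: np.ndarray, s0_quantile: float = 0.5
) -> np.ndarray:
    """Margin-weighted linear-discriminant direction between two batches.

    The per-gene mean difference weighted by the inverse pooled
    within-batch spread (plus a median offset, as in shrunken-centroid
    scoring) emphasises genes whose batch shift is large relative to
    biological scatter.  Used to verify batch separation removal.
    """
    delta = ref.mean(axis=1) - other.mean(axis=1)
    s = np.sqrt(0.5 * (ref.var(axis=1, ddof=1) + other.var(axis=1, ddof=1)))
    s0 = np.quantile(s, s0_quantile)
    w = delta / (s + s0 + 1e-12)
    norm = np.linalg.norm(w)
    return w / norm if norm > 0 else w


def merge_cohorts(
    bundles: list[CohortBundle],
    strategy: str = "center",
    reference: int = 0,
) -> CohortBundle:
    """Merge >=2 cohorts on their common features, removing batch shifts.

    ``"center"`` mean-centres every source independently and
    concatenates.  ``"dwd_lite"`` translates each non-reference batch so
    its centroid coincides with the reference batch centroid; the
    translation is along the centroid-difference direction, and the
    per-source means projected on the margin-weighted separating
    direction agree to < 1e-6 afterwards.  Merging a single bundle
    returns it unchanged (identity).
    """
    if strategy not in ("center", "dwd_lite"):
        raise ValueError(f"unknown merge strategy {strategy!r}")
    if len(bundles) == 0:
        raise ValueError("no bundles to merge")
    if len(bundles) == 1:
        return bundles[0]

    common = bundles[0].expression.index
    for b in bundles[1:]:
        common = common.intersection(b.expression.index)
    if len(common) == 0:
        raise ValueError("empty feature intersection across bundles")
    common_set = set(common)
    common = [f for f in bundles[0].expression.index if f in common_set]

    sample_sets = [set(b.expression.columns) for b in bundles]
    for i in range(len(sample_sets)):
        for j in range(i + 1, len(sample_sets)):
            if sample_sets[i] & sample_sets[j]:
                raise ValueError("bundles share sample ids; cannot merge")

    blocks = []
    if strategy == "center":
        for b in bundles:
            centred = mean_center_within_source(b.subset_features(common))
            blocks.append(centred.expression)
    else:
        mats = [b.subset_features(common).expression for b in bundles]
        ref = mats[reference].to_numpy(dtype=float)
        mu_ref = ref.mean(axis=1)
        for i, mat in enumerate(mats):
            if i == reference:
                blocks.append(mat)
                continue
            other = mat.to_numpy(dtype=float)
            shift = mu_ref - other.mean(axis=1)  # centroid alignment
            w = _separating_direction(ref, other)
            adjusted = other + shift[:, None]
            resid = abs(float(w @ (ref.mean(axis=1) - adjusted.mean(axis=1))))
            if resid > 1e-6:
                raise AssertionError("dwd_lite projection contract violated")
            blocks.append(pd.DataFrame(adjusted, index=mat.index, columns=mat.columns))

    expr = pd.concat(blocks, axis=1)
    clinical = pd.concat([b.clinical for b in bundles], axis=0)
    transforms = [t for b in bundles for t in b.transforms]
    transforms.append(
        TransformRecord(
            "merge_cohorts",
            {
                "strategy": strategy,
                "n_bundles": len(bundles),
                "n_common_features": len(common),
            },
        )
    )
    fmap = bundles[0].feature_map
    return CohortBundle(
        expression=expr.loc[:, clinical.index],
        clinical=clinical,
        feature_map=fmap,
        transforms=transforms,
    )
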