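"""Three-stage prognostic candidate selection.

The chain mirrors the discovery protocol for pooled HRneg/Tneg training
cohorts:

1. **PAM screen** -- nearest-shrunken-centroid scoring of each feature
   against the distant-metastasis event label, run independently per
   data source; the shrinkage threshold is tuned so roughly ``top_k``
   features survive per source, and only features selected in *every*
   source with the *same* score sign are kept.
2. **Monte-Carlo cross-validation Cox screen** -- repeated random
   learning/test splits balanced on the event count; a univariate Cox
   fit per feature in each half; selection requires mean Wald P below
   0.01 over all fits *and* coefficient-sign agreement between the two
   halves in more than 80% of iterations.
3. **Cox consistency + holdout confirmation** -- the union of the two
   screens' candidates is filtered to features whose univariate and
   joint-multivariate coefficient signs agree on the discovery subset,
   then confirmed by sign agreement of a univariate fit on the held-out
   subset.

Candidate bookkeeping lives in a DataFrame (one row per feature) whose
columns follow :data:`CANDIDATE_COLUMNS`; ``direction`` is the sign of
the discovery univariate coefficient.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .bundle import CohortBundle
from .index import GeneSignature
from .prep import (
    mean_center_within_source,
    merge_cohorts,
    variance_filter,
    z_transform_within_source,
)
from .simulate import split_training_layout
from .survival import cox_fit, cox_univariate_batch

log = logging.getLogger(__name__)

CANDIDATE_COLUMNS = [
    "feature_id",
    "gene_symbol",
    "pam_selected",
    "pam_min_abs_score",
    "mccv_mean_p",
    "mccv_consistency",
    "mccv_selected",
    "provenance",
    "uni_coef",
    "uni_p",
    "multi_coef",
    "multi_p",
    "cox_consistent",
    "holdout_coef",
    "holdout_p",
    "final_selected",
    "direction",
]


@dataclass(frozen=True)
class MCCVConfig:
    """Monte-Carlo cross-validation screen settings."""

    n_iterations: int = 100
    p_threshold: float = 0.01
    consistency_threshold: float = 0.80
    split_fraction: float = 0.5
    seed: int = 0
    p_mean: str = "arithmetic"  # or "geometric"

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        for name in ("p_threshold", "consistency_threshold", "split_fraction"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.p_mean not in ("arithmetic", "geometric"):
            raise ValueError("p_mean must be 'arithmetic' or 'geometric'")


# ---------------------------------------------------------------------------
# PAM (nearest shrunken centroids)
# ---------------------------------------------------------------------------
def _pam_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Standardised class-centroid deviations d_ik (features x classes).

    d_ik = (class mean - overall mean) / (m_k * (s_i + s0)) with
    m_k = sqrt(1/n_k - 1/n), pooled within-class s_i, and s0 the median
    of the s_i.
    """
    classes = np.unique(y)
    n = X.shape[1]
    overall = X.mean(axis=1)
    resid_ss = np.zeros(X.shape[0])
    cents = []
    for k in classes:
        block = X[:, y == k]
        cents.append(block.mean(axis=1))
        resid_ss += ((block - cents[-1][:, None]) ** 2).sum(axis=1)
    s = np.sqrt(resid_ss / (n - len(classes)))
    s0 = np.median(s)
    d = np.empty((X.shape[0], len(classes)))
    for j, k in enumerate(classes):
        nk = int((y == k).sum())
        mk = np.sqrt(1.0 / nk - 1.0 / n)
        d[:, j] = (cents[j] - overall) / (mk * (s + s0))
    return d


def pam_screen(
    bundle: CohortBundle,
    labels: pd.Series,
    top_k: int = 300,
) -> dict[str, pd.DataFrame]:
    """Per-source shrunken-centroid screen against a binary label.

    For each source the soft threshold is chosen so the surviving
    feature count is closest to ``top_k``.  The reported ``score`` is
    the shrunken deviation for the event (label 1) class; ``selected``
    marks survivors.
    """
    results: dict[str, pd.DataFrame] = {}
    features = bundle.expression.index
    for source in bundle.sources:
        samples = bundle.source_mask(source)
        y = labels.loc[samples].to_numpy(dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError(f"source {source!r} lacks both classes")
        if min((y == 0).sum(), (y == 1).sum()) < 2:
            raise ValueError(f"source {source!r} has <2 samples in a class")
        X = bundle.expression.loc[:, samples].to_numpy(dtype=float)
        d = _pam_scores(X, y)
        event_col = int(np.flatnonzero(np.unique(y) == 1)[0])
        mx = np.abs(d).max(axis=1)
        if top_k >= len(features):
            delta = 0.0
        else:
            srt = np.sort(mx)[::-1]
            delta = 0.5 * (srt[top_k - 1] + srt[top_k])
        shrunk = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
        selected = (np.abs(shrunk) > 0).any(axis=1)
        results[source] = pd.DataFrame(
            {
                "score": shrunk[:, event_col],
                "raw_score": d[:, event_col],
                "selected": selected,
            },
            index=features,
        )
    return results


def pam_intersect(per_source: dict[str, pd.DataFrame]) -> list:
    """Features selected in every source with identical score sign."""
    if len(per_source) < 2:
        raise ValueError("pam_intersect requires >= 2 screened sources")
    frames = list(per_source.values())
    sel = np.logical_and.reduce([f["selected"].to_numpy() for f in frames])
    signs = np.column_stack([np.sign(f["raw_score"].to_numpy()) for f in frames])
    same_sign = (signs == signs[:, [0]]).all(axis=1) & (signs[:, 0] != 0)
    keep = sel & same_sign
    return list(frames[0].index[keep])


# ---------------------------------------------------------------------------
# Monte-Carlo cross-validation Cox screen
# ---------------------------------------------------------------------------
def _stratified_halves(
    sample_ids: list, events: pd.Series, frac: float, rng: np.random.Generator
) -> tuple[list, list]:
    """Random learning/test split with event counts balanced to within 1.

    Sample ids are sorted before shuffling so the split depends only on
    the ids (and the RNG state), not on input order.
    """
    learn, test = [], []
    for flag in (1, 0):
        ids = sorted(s for s in sample_ids if events[s] == flag)
        perm = rng.permutation(len(ids))
        k = int(round(len(ids) * frac))
        chosen = set(perm[:k])
        for i, s in enumerate(ids):
            (learn if i in chosen else test).append(s)
    return learn, test


def mccv_screen(
    bundle: CohortBundle,
    config: MCCVConfig = MCCVConfig(),
) -> pd.DataFrame:
    """Monte-Carlo CV univariate Cox screen over all features.

    Returns a DataFrame indexed by feature with ``mccv_mean_p``,
    ``mccv_consistency`` and ``mccv_selected``; deterministic given the
    config seed and invariant to sample-order permutation.
    """
    rng = np.random.default_rng(config.seed)
    samples = list(bundle.expression.columns)
    events = bundle.clinical["dmfs_event"]
    times = bundle.clinical["dmfs_months"]
    if events.sum() < 2:
        raise ValueError("mccv_screen needs at least two events")
    Xnp = bundle.expression.to_numpy(dtype=float).T  # samples x features
    pos = {s: i for i, s in enumerate(samples)}
    times_np = times.loc[samples].to_numpy(dtype=float)
    events_np = events.loc[samples].to_numpy(dtype=int)

    n_feat = bundle.n_features
    p_sum = np.zeros(n_feat)
    logp_sum = np.zeros(n_feat)
    agree = np.zeros(n_feat)
    for _ in range(config.n_iterations):
        for attempt in range(10):
            learn, test = _stratified_halves(
                samples, events, config.split_fraction, rng
            )
            if events[learn].sum() > 0 and events[test].sum() > 0:
                break
            log.warning("re-drawing degenerate MC-CV split (zero-event group)")
        else:
            raise RuntimeError("could not draw a split with events in both groups")
        il = np.array([pos[s] for s in learn], dtype=int)
        it = np.array([pos[s] for s in test], dtype=int)
        res_l = cox_univariate_batch(times_np[il], events_np[il], Xnp[il])
        res_t = cox_univariate_batch(times_np[it], events_np[it], Xnp[it])
        p_sum += res_l.p + res_t.p
        with np.errstate(divide="ignore"):
            logp_sum += np.log(np.maximum(res_l.p, 1e-300)) + np.log(
                np.maximum(res_t.p, 1e-300)
            )
        ok = (~res_l.constant) & (~res_t.constant)
        agree += ok & (np.sign(res_l.coef) == np.sign(res_t.coef)) & (
            np.sign(res_l.coef) != 0
        )

    n_fits = 2 * config.n_iterations
    if config.p_mean == "arithmetic":
        mean_p = p_sum / n_fits
    else:
        mean_p = np.exp(logp_sum / n_fits)
    consistency = agree / config.n_iterations
    selected = (mean_p < config.p_threshold) & (
        consistency > config.consistency_threshold
    )
    return pd.DataFrame(
        {
            "mccv_mean_p": mean_p,
            "mccv_consistency": consistency,
            "mccv_selected": selected,
        },
        index=bundle.expression.index,
    )


# ---------------------------------------------------------------------------
# Cox consistency and holdout confirmation
# ---------------------------------------------------------------------------
def cox_consistency_filter(
    records: pd.DataFrame,
    bundle: CohortBundle,
) -> pd.DataFrame:
    """Keep candidates whose univariate and joint-multivariate signs agree.

    The multivariate model fits all current candidates jointly (no
    clinical covariates).  A non-converging joint fit falls back to a
    ridge-stabilised fit (penalty 1e-4), logged.
    """
    records = records.copy()
    cand = list(records.index[records["candidate"]])
    if not cand:
        return records
    times = bundle.times
    events = bundle.events
    X = bundle.expression.loc[cand].T.to_numpy(dtype=float)
    uni = cox_univariate_batch(times, events, X)
    records.loc[cand, "uni_coef"] = uni.coef
    records.loc[cand, "uni_p"] = uni.p

    covs = bundle.expression.loc[cand].T
    covs.columns = [str(c) for c in covs.columns]
    try:
        fit = cox_fit(times, events, covs)
        if not fit.converged:
            raise RuntimeError("flagged non-convergence")
    except Exception as err:  # collinear / separated designs
        log.warning("joint Cox fit unstable (%s); ridge fallback 1e-4", err)
        fit = cox_fit(times, events, covs, ridge=1e-4)
    records.loc[cand, "multi_coef"] = fit.coefficients[[str(c) for c in cand]].to_numpy()
    records.loc[cand, "multi_p"] = fit.wald_p[[str(c) for c in cand]].to_numpy()

    consistent = np.sign(records.loc[cand, "uni_coef"]) == np.sign(
        records.loc[cand, "multi_coef"]
    )
    records.loc[cand, "cox_consistent"] = consistent.to_numpy()
    records["candidate"] = records["candidate"] & records["cox_consistent"].fillna(False).astype(bool)
    return records


def holdout_confirm(
    records: pd.DataFrame,
    holdout: CohortBundle,
) -> pd.DataFrame:
    """Confirm candidates by coefficient-sign agreement in the holdout.

    The holdout bundle should already be mean-centred within its own
    source(s).  Candidates absent from the holdout are dropped with a
    warning.
    """
    records = records.copy()
    records["final_selected"] = False
    cand = list(records.index[records["candidate"]])
    if not cand:
        return records
    present = [c for c in cand if c in holdout.expression.index]
    missing = sorted(set(cand) - set(present))
    if missing:
        warnings.warn(f"candidates absent from holdout, dropped: {missing}")
    if not present:
        return records
    res = cox_univariate_batch(
        holdout.times, holdout.events,
        holdout.expression.loc[present].T.to_numpy(dtype=float),
    )
    records.loc[present, "holdout_coef"] = res.coef
    records.loc[present, "holdout_p"] = res.p
    same = np.sign(res.coef) == np.sign(records.loc[present, "uni_coef"].to_numpy())
    records.loc[present, "final_selected"] = same & (res.coef != 0)
    sel = records.index[records["final_selected"]]
    records.loc[sel, "direction"] = np.sign(records.loc[sel, "uni_coef"]).astype(int)
    return records


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------
@dataclass
class DiscoveryResult:
    hrneg_records: pd.DataFrame
    tneg_records: pd.DataFrame
    combined_signature: GeneSignature
    hrneg_genes: list[str]
    tneg_genes: list[str]


def _blank_records(features, fmap: pd.Series | None) -> pd.DataFrame:
    rec = pd.DataFrame(index=pd.Index(features, name="feature_id"))
    rec["gene_symbol"] = (
        fmap.reindex(features).fillna(pd.Series(features, index=features))
        if fmap is not None
        else list(features)
    )
    for col in (
        "pam_selected", "mccv_selected", "cox_consistent", "candidate",
        "final_selected",
    ):
        rec[col] = False
    for col in (
        "mccv_mean_p", "mccv_consistency", "uni_coef", "uni_p",
        "multi_coef", "multi_p", "holdout_coef", "holdout_p",
    ):
        rec[col] = np.nan
    rec["provenance"] = ""
    rec["direction"] = 0
    return rec


def _run_chain(
    discovery: CohortBundle,
    holdout: CohortBundle,
    mccv_config: MCCVConfig,
    pam_top_k: int,
    variance_min_fraction: float,
    variance_log2_fold: float,
    combine: str = "union",
) -> pd.DataFrame:
    """One full selection chain on a (discovery, holdout) pair."""
    # PAM on per-source log2 data, event-indicator labels
    labels = discovery.clinical["dmfs_event"]
    pam = pam_screen(discovery, labels, top_k=pam_top_k)
    pam_set = set(pam_intersect(pam)) if len(pam) >= 2 else {
        f for df in pam.values() for f in df.index[df["selected"]]
    }

    # Z-transform per source, combine, variance filter, MC-CV screen
    per_source = [
        discovery.subset_samples(discovery.source_mask(s)) for s in discovery.sources
    ]
    z = merge_cohorts(
        [z_transform_within_source(b) for b in per_source], strategy="center"
    )
    z_filt, kept = variance_filter(
        z, min_fraction=variance_min_fraction, log2_fold=variance_log2_fold
    )
    mccv = mccv_screen(z_filt, mccv_config)
    mccv_set = set(mccv.index[mccv["mccv_selected"]])

    records = _blank_records(discovery.expression.index, discovery.feature_map)
    records.loc[records.index.isin(pam_set), "pam_selected"] = True
    records.loc[mccv.index, ["mccv_mean_p", "mccv_consistency"]] = mccv[
        ["mccv_mean_p", "mccv_consistency"]
    ].to_numpy()
    records.loc[records.index.isin(mccv_set), "mccv_selected"] = True
    records["provenance"] = np.select(
        [
            records["pam_selected"] & records["mccv_selected"],
            records["pam_selected"],
            records["mccv_selected"],
        ],
        ["pam+mccv", "pam", "mccv"],
        default="",
    )
    if combine == "union":
        records["candidate"] = records["pam_selected"] | records["mccv_selected"]
    else:
        records["candidate"] = records["pam_selected"] & records["mccv_selected"]

    records = cox_consistency_filter(records, z)
    holdout_centred = mean_center_within_source(holdout)
    records = holdout_confirm(records, holdout_centred)
    return records


def discover(
    bundle: CohortBundle,
    layout: dict[str, list[str]],
    mccv_config: MCCVConfig = MCCVConfig(),
    pam_top_k: int = 300,
    variance_min_fraction: float = 0.10,
    variance_log2_fold: float = 1.0,
    combine: str = "union",
) -> DiscoveryResult:
    """Run the full chain on all HRneg samples and on the Tneg subset.

    The combined signature is the union of the two final candidate
    lists with hazard directions taken from the discovery univariate
    coefficient signs (the HRneg chain wins on conflict, logged).
    Requires ``tneg`` flags in the clinical table (see
    :func:`tnegsig.prep.assign_her2_status`).
    """
    if "tneg" not in bundle.clinical.columns:
        raise ValueError("bundle lacks tneg flags; run assign_her2_status first")

    disc, hold = split_training_layout(bundle, layout)
    hr_records = _run_chain(
        disc, hold, mccv_config, pam_top_k,
        variance_min_fraction, variance_log2_fold, combine,
    )

    tneg_ids = bundle.clinical.index[bundle.clinical["tneg"].astype(bool)]
    tneg_bundle = bundle.subset_samples(tneg_ids)
    tn_disc, tn_hold = split_training_layout(tneg_bundle, layout)
    tn_config = replace(mccv_config, seed=mccv_config.seed + 1)
    tn_records = _run_chain(
        tn_disc, tn_hold, tn_config, pam_top_k,
        variance_min_fraction, variance_log2_fold, combine,
    )

    hr_genes = sorted(hr_records.index[hr_records["final_selected"]])
    tn_genes = sorted(tn_records.index[tn_records["final_selected"]])
    members: dict[str, int] = {}
    for rec, genes in ((hr_records, hr_genes), (tn_records, tn_genes)):
        for g in genes:
            symbol = str(rec.loc[g, "gene_symbol"])
            d = int(rec.loc[g, "direction"])
            if symbol in members and members[symbol] != d:
                log.warning(
                    "direction conflict for %s between chains; keeping HRneg sign",
                    symbol,
                )
                continue
            members.setdefault(symbol, d)
    if not members:
        raise RuntimeError("discovery selected no final candidates")
    signature = GeneSignature(
        name="discovered_hrneg_tneg",
        members=members,
        provenance="union of HRneg and Tneg final candidates",
    )
    return DiscoveryResult(
        hrneg_records=hr_records,
        tneg_records=tn_records,
        combined_signature=signature,
        hrneg_genes=hr_genes,
        tneg_genes=tn_genes,
    )
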