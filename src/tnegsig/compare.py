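"""Multi-signature prognostic comparison on a common cohort.

External signatures (NKI-70, MS-14, CSR/wound, ONCO-RS, GGI, IR-7,
STAT1/IFN clusters, ...) enter as direction-annotated gene lists and are
all scored with the same sign-corrected index formula; native scoring
algorithms of the commercial predictors are deliberately out of scope.
Comparisons use the *median* cut for every signature -- including the
in-house one -- so no signature benefits from its own tuned cut-point.

Lymphocyte-infiltration surrogates (T-cell / B-cell signature scores)
are direction-free unweighted mean expressions; because prognostic
indices are sign-corrected toward hazard, negative correlations with
the lymphocyte scores are the expected direction for immune-derived
protective signatures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bundle import CohortBundle
from .index import GeneSignature, IndexVector, compute_index, dichotomize


def map_signature(
    signature: GeneSignature, bundle: CohortBundle
) -> tuple[GeneSignature, dict]:
    """Restrict a signature to the cohort's gene symbols.

    Returns the mapped signature and a coverage report; zero coverage
    raises (the restriction error names the signature).
    """
    mapped = signature.restrict(bundle.expression.index)
    coverage = {
        "signature": signature.name,
        "n_total": len(signature),
        "n_mapped": len(mapped),
        "mapped_fraction": len(mapped) / len(signature),
        "missing": sorted(set(signature.members) - set(mapped.members)),
    }
    return mapped, coverage


def compare_prognosis(
    bundle: CohortBundle,
    library: dict[str, GeneSignature],
    percentile: float = 50.0,
) -> pd.DataFrame:
    """Dichotomise the cohort by each signature index at a common cut.

    One row per signature: mapped count, HR (high vs low) with 95% CI
    and Wald P from a Cox fit on the group indicator, plus the log-rank
    P of the Kaplan-Meier split.
    """
    times = bundle.times
    events = bundle.events
    rows = []
    for name, sig in library.items():
        mapped, cov = map_signature(sig, bundle)
        idx = compute_index(bundle, mapped)
        _, cp = dichotomize(idx, times, events, percentile=percentile)
        rows.append(
            {
                "signature": name,
                "n_mapped": cov["n_mapped"],
                "mapped_fraction": cov["mapped_fraction"],
                "hr": cp.hr_high_vs_low,
                "ci_lower": cp.hr_ci95[0],
                "ci_upper": cp.hr_ci95[1],
                "cox_p": cp.cox_p,
                "logrank_p": cp.logrank_p,
                "n_high": cp.n_high,
                "n_low": cp.n_low,
            }
        )
    return pd.DataFrame(rows).set_index("signature")


def signature_indices(
    bundle: CohortBundle, library: dict[str, GeneSignature]
) -> pd.DataFrame:
    """Per-sample index for every signature (samples x signatures)."""
    cols = {}
    for name, sig in library.items():
        mapped, _ = map_signature(sig, bundle)
        cols[name] = compute_index(bundle, mapped).scores
    return pd.DataFrame(cols)


def correlate_indices(
    indices: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations between signature indices.

    Returns (R, P) DataFrames; P values from the t distribution on n-2
    degrees of freedom.  Constant indices yield NaN and are effectively
    flagged by the caller.
    """
    names = list(indices.columns)
    if len(names) < 2:
        raise ValueError("correlate_indices requires >= 2 indices")
    n = len(indices)
    R = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    P = pd.DataFrame(np.zeros((len(names), len(names))), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            x = indices[a].to_numpy(dtype=float)
            y = indices[b].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(x, y)
            R.loc[a, b] = R.loc[b, a] = r
            P.loc[a, b] = P.loc[b, a] = p
    np.fill_diagonal(P.values, 0.0)
    return R, P


def cross_cohort_consistency(R1: pd.DataFrame, R2: pd.DataFrame) -> pd.DataFrame:
    """Flag signature pairs whose correlation signs agree across cohorts.

    True where sign(R1) == sign(R2) (both non-zero); symmetric with a
    True diagonal.  Inconsistent pairs are the ones a correlation
    heatmap would grey out.
    """
    common = R1.index.intersection(R2.index)
    a = np.sign(R1.loc[common, common].to_numpy())
    b = np.sign(R2.loc[common, common].to_numpy())
    consistent = (a == b) & (a != 0)
    np.fill_diagonal(consistent, True)
    return pd.DataFrame(consistent, index=common, columns=common)


@dataclass
class LymphocyteReport:
    t_scores: pd.Series
    b_scores: pd.Series
    correlations: pd.DataFrame  # rows: (T, B) x index names; cols: r, p


def mean_expression_score(bundle: CohortBundle, genes) -> pd.Series:
    """Direction-free unweighted mean expression of the mapped genes."""
    present = [g for g in genes if g in bundle.expression.index]
    if not present:
        raise ValueError("no lymphocyte-signature gene maps to the cohort")
    return bundle.expression.loc[present].mean(axis=0)


def lymphocyte_scores(
    bundle: CohortBundle,
    t_signature: GeneSignature,
    b_signature: GeneSignature,
    indices: dict[str, IndexVector] | pd.DataFrame,
) -> LymphocyteReport:
    """T-/B-cell infiltration surrogates and their index correlations."""
    t_scores = mean_expression_score(bundle, t_signature.members)
    b_scores = mean_expression_score(bundle, b_signature.members)
    if isinstance(indices, pd.DataFrame):
        index_map = {c: indices[c] for c in indices.columns}
    else:
        index_map = {k: v.scores for k, v in indices.items()}
    rows = []
    for cell, score in (("T", t_scores), ("B", b_scores)):
        for name, idx in index_map.items():
            aligned = idx.loc[score.index]
            r, p = stats.pearsonr(score.to_numpy(), aligned.to_numpy())
            rows.append({"lymphocyte": cell, "index": name, "r": r, "p": p})
    return LymphocyteReport(
        t_scores=t_scores,
        b_scores=b_scores,
        correlations=pd.DataFrame(rows).set_index(["lymphocyte", "index"]),
    )
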