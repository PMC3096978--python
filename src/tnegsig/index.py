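"""Sign-corrected composite index and its downstream survival use.

The index of a signature on sample ``s`` is

    score_s = ( sum_{i in P} x_is  -  sum_{j in N} x_js ) / n

where ``P``/``N`` are the signature genes positively/negatively
associated with hazard, ``x`` the (merged, batch-adjusted) log2
expression, and ``n`` the number of signature genes actually present in
the cohort.  Genes are equally weighted by construction; higher score
means worse predicted prognosis.

Dichotomisation uses the ">= cut" rule: with distinct index values and
a requested percentile ``pct``, the low (good-prognosis) group has
exactly ``ceil(n * pct / 100)`` samples.  Cut-point optimisation scans
every distinct index value whose implied split lies within the 20th-80th
percentile band and minimises the log-rank P; ties break toward the cut
closest to the 75th percentile, which is empirically near-optimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .bundle import CohortBundle
from .survival import cox_fit, cox_univariate_batch, logrank_grid, logrank_test


# ---------------------------------------------------------------------------
# signature objects
# ---------------------------------------------------------------------------
@dataclass
class GeneSignature:
    """Named gene set annotated with hazard direction (+1 or -1)."""

    name: str
    members: dict[str, int]  # gene symbol -> direction
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"signature {self.name!r} is empty")
        bad = {g: d for g, d in self.members.items() if d not in (+1, -1)}
        if bad:
            raise ValueError(f"directions must be +1/-1, got {bad}")

    @property
    def positive(self) -> list[str]:
        """Set P: hazard-increasing genes."""
        return [g for g, d in self.members.items() if d == +1]

    @property
    def negative(self) -> list[str]:
        """Set N: hazard-decreasing (protective) genes."""
        return [g for g, d in self.members.items() if d == -1]

    def __len__(self) -> int:
        return len(self.members)

    def restrict(self, symbols, name: str | None = None) -> "GeneSignature":
        present = set(symbols)
        keep = {g: d for g, d in self.members.items() if g in present}
        if not keep:
            raise ValueError(
                f"signature {self.name!r}: no member maps to the cohort"
            )
        return GeneSignature(
            name=name or self.name,
            members=keep,
            provenance=self.provenance,
        )

    @classmethod
    def from_tsv(cls, path, name: str | None = None) -> "GeneSignature":
        df = pd.read_csv(path, sep="\t")
        if not {"gene_symbol", "direction"} <= set(df.columns):
            raise ValueError("signature TSV needs gene_symbol and direction columns")
        if df["gene_symbol"].duplicated().any():
            raise ValueError("duplicate gene symbols in signature file")
        members = dict(zip(df["gene_symbol"], df["direction"].astype(int)))
        return cls(name=name or str(path), members=members, provenance=str(path))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"gene_symbol": list(self.members), "direction": list(self.members.values())}
        ).to_csv(path, sep="\t", index=False)


#: Signatures shipped with the package (reconstructed from the published
#: candidate tables): the combined 14-gene HRneg/Tneg list, the 11-gene
#: HRneg list, the 7-gene Tneg list and the 7-gene stepwise-prioritised
#: subset.
PACKAGED_SIGNATURES = {
    "hrneg_tneg_14": "hrneg_tneg_14.tsv",
    "hrneg_11": "hrneg_11.tsv",
    "tneg_7": "tneg_7.tsv",
    "hrneg_tneg_step7": "hrneg_tneg_step7.tsv",
}


def load_packaged_signature(key: str) -> GeneSignature:
    if key not in PACKAGED_SIGNATURES:
        raise KeyError(f"unknown packaged signature {key!r}")
    ref = resources.files("tnegsig").joinpath("signatures", PACKAGED_SIGNATURES[key])
    with resources.as_file(ref) as path:
        return GeneSignature.from_tsv(path, name=key)


# ---------------------------------------------------------------------------
# index computation
# ---------------------------------------------------------------------------
@dataclass
class IndexVector:
    """Per-sample composite scores plus mapping bookkeeping."""

    scores: pd.Series
    n_mapped: int
    mapped_fraction: float
    signature_name: str = ""

    def __post_init__(self) -> None:
        if self.n_mapped < 1:
            raise ValueError("index requires at least one mapped gene")
        if not np.all(np.isfinite(self.scores.to_numpy(dtype=float))):
            raise ValueError("index scores must be finite")


def compute_index(bundle: CohortBundle, signature: GeneSignature) -> IndexVector:
    """Evaluate the sign-corrected index; absent genes reduce ``n``."""
    present = signature.restrict(bundle.expression.index)
    pos = present.positive
    neg = present.negative
    n_mapped = len(present)
    expr = bundle.expression
    total = pd.Series(0.0, index=expr.columns)
    if pos:
        total = total + expr.loc[pos].sum(axis=0)
    if neg:
        total = total - expr.loc[neg].sum(axis=0)
    scores = total / n_mapped
    return IndexVector(
        scores=scores,
        n_mapped=n_mapped,
        mapped_fraction=n_mapped / len(signature),
        signature_name=signature.name,
    )


# ---------------------------------------------------------------------------
# dichotomisation and cut-point search
# ---------------------------------------------------------------------------
@dataclass
class CutpointResult:
    cut_value: float
    percentile: float
    n_high: int
    n_low: int
    logrank_chi2: float
    logrank_p: float
    hr_high_vs_low: float = float("nan")
    hr_ci95: tuple[float, float] = (float("nan"), float("nan"))
    cox_p: float = float("nan")
    grid: pd.DataFrame | None = field(default=None, repr=False)


def _groups_from_cut(scores: np.ndarray, cut: float) -> np.ndarray:
    return scores >= cut  # high (poor-prognosis) group


def dichotomize(
    index: IndexVector,
    times,
    events,
    percentile: float | None = 50.0,
    value: float | None = None,
) -> tuple[pd.Series, CutpointResult]:
    """Split a cohort into high/low index groups and test the split.

    Either a percentile (median 50, upper third quartile 75) or an
    explicit cut value may be given.  High group = index >= cut.
    """
    scores = index.scores.to_numpy(dtype=float)
    n = len(scores)
    if n < 4:
        raise ValueError("dichotomize requires n >= 4")
    if value is not None:
        cut = float(value)
    else:
        if percentile is None or not (0 < percentile < 100):
            raise ValueError("percentile must lie strictly between 0 and 100")
        k = math.ceil(n * percentile / 100.0)
        srt = np.sort(scores)
        if k >= n:
            k = n - 1
        cut = float(srt[k])
    high = _groups_from_cut(scores, cut)
    if high.all() or not high.any():
        raise ValueError("no valid cut: dichotomization yields an empty group")

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    chi2, p = logrank_test(times, events, high.astype(int))
    fit = cox_fit(times, events, pd.DataFrame({"high": high.astype(float)}))
    res = CutpointResult(
        cut_value=cut,
        percentile=100.0 * float((scores < cut).mean()),
        n_high=int(high.sum()),
        n_low=int((~high).sum()),
        logrank_chi2=chi2,
        logrank_p=p,
        hr_high_vs_low=float(fit.hr["high"]),
        hr_ci95=(
            float(fit.ci95.loc["high", "lower"]),
            float(fit.ci95.loc["high", "upper"]),
        ),
        cox_p=float(fit.wald_p["high"]),
    )
    groups = pd.Series(
        np.where(high, "high", "low"), index=index.scores.index, name="index_group"
    )
    return groups, res


def optimize_cutpoint(
    index: IndexVector,
    times,
    events,
    lower_pct: float = 20.0,
    upper_pct: float = 80.0,
) -> CutpointResult:
    """Log-rank-minimising cut restricted to a central percentile band.

    Every distinct index value whose implied low-group fraction lies in
    [lower_pct, upper_pct] is evaluated; the grid of (cut, percentile,
    chi2, P) is returned for plotting.  The optimised P is exploratory:
    no multiplicity correction is applied inside the search.
    """
    scores = index.scores.to_numpy(dtype=float)
    n = len(scores)
    cuts = np.unique(scores)
    low_frac = np.array([(scores < c).mean() for c in cuts])
    ok = (low_frac * 100 >= lower_pct) & (low_frac * 100 <= upper_pct)
    cuts = cuts[ok]
    pct = low_frac[ok] * 100
    if cuts.size == 0:
        raise ValueError("no valid cuts within the percentile band")

    membership = scores[:, None] >= cuts[None, :]
    chi2, p = logrank_grid(times, events, membership)
    best_p = p.min()
    tied = np.flatnonzero(p <= best_p + 1e-15)
    best = tied[np.argmin(np.abs(pct[tied] - 75.0))]

    grid = pd.DataFrame(
        {"cut_value": cuts, "percentile": pct, "logrank_chi2": chi2, "logrank_p": p}
    )
    high = membership[:, best]
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    fit = cox_fit(times, events, pd.DataFrame({"high": high.astype(float)}))
    return CutpointResult(
        cut_value=float(cuts[best]),
        percentile=float(pct[best]),
        n_high=int(high.sum()),
        n_low=int((~high).sum()),
        logrank_chi2=float(chi2[best]),
        logrank_p=float(p[best]),
        hr_high_vs_low=float(fit.hr["high"]),
        hr_ci95=(
            float(fit.ci95.loc["high", "lower"]),
            float(fit.ci95.loc["high", "upper"]),
        ),
        cox_p=float(fit.wald_p["high"]),
        grid=grid,
    )


# ---------------------------------------------------------------------------
# stepwise prioritisation
# ---------------------------------------------------------------------------
@dataclass
class StepwiseResult:
    """Greedy gene ordering with per-step continuous-index Cox stats."""

    order: list[str]
    steps: pd.DataFrame  # step, gene, coef, p (index Cox, continuous)
    best_subset: list[str]


def _signed_matrix(bundle: CohortBundle, members: dict[str, int]) -> pd.DataFrame:
    genes = [g for g in members if g in bundle.expression.index]
    mat = bundle.expression.loc[genes].T.copy()
    for g in genes:
        mat[g] = mat[g] * members[g]
    return mat


def stepwise_addition(
    candidates: dict[str, int],
    bundle: CohortBundle,
    times,
    events,
    score: str = "p",
) -> StepwiseResult:
    """Greedy forward ordering of signature candidates.

    Starts from the candidate whose single-gene index has the minimum
    univariate Cox Wald P (or largest |coefficient| with ``score="coef"``)
    and at each step adds the candidate whose inclusion gives the best
    continuous-index Cox score.  The best subset is the prefix with the
    global minimum P over steps.
    """
    if not candidates:
        raise ValueError("no candidates to order")
    signed = _signed_matrix(bundle, candidates)
    genes = list(signed.columns)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)

    remaining = list(genes)
    chosen: list[str] = []
    running = np.zeros(len(signed))
    rows = []
    while remaining:
        trial = np.column_stack(
            [(running + signed[g].to_numpy()) / (len(chosen) + 1) for g in remaining]
        )
        res = cox_univariate_batch(times, events, trial)
        if score == "coef":
            rank = -np.abs(res.coef)
        else:
            rank = res.p
        order = np.lexsort((np.array(remaining, dtype=object), rank))
        best = order[0]
        g = remaining[best]
        chosen.append(g)
        running = running + signed[g].to_numpy()
        rows.append(
            {
                "step": len(chosen),
                "gene": g,
                "coef": float(res.coef[best]),
                "p": float(res.p[best]),
            }
        )
        remaining.remove(g)
    steps = pd.DataFrame(rows)
    best_k = int(steps["p"].idxmin())
    return StepwiseResult(
        order=chosen,
        steps=steps,
        best_subset=chosen[: best_k + 1],
    )


def stepwise_subtraction(
    signature: GeneSignature,
    bundle: CohortBundle,
    times,
    events,
    score: str = "p",
) -> StepwiseResult:
    """Greedy backward removal from a full signature.

    At each step the gene whose removal minimises the continuous-index
    Cox P is dropped (ties lexicographically); a size-1 signature yields
    an empty removal sequence.
    """
    members = {g: d for g, d in signature.members.items() if g in bundle.expression.index}
    if not members:
        raise ValueError(f"signature {signature.name!r} maps no genes")
    signed = _signed_matrix(bundle, members)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)

    current = sorted(members)
    rows = []
    removed: list[str] = []
    while len(current) > 1:
        trial = np.column_stack(
            [
                signed[[g for g in current if g != drop]].to_numpy().sum(axis=1)
                / (len(current) - 1)
                for drop in current
            ]
        )
        res = cox_univariate_batch(times, events, trial)
        if score == "coef":
            rank = -np.abs(res.coef)
        else:
            rank = res.p
        order = np.lexsort((np.array(current, dtype=object), rank))
        best = order[0]
        drop = current[best]
        removed.append(drop)
        rows.append(
            {
                "step": len(removed),
                "gene": drop,
                "coef": float(res.coef[best]),
                "p": float(res.p[best]),
            }
        )
        current.remove(drop)
    steps = pd.DataFrame(rows, columns=["step", "gene", "coef", "p"])
    if len(steps):
        best_k = int(steps["p"].idxmin())
        surviving = sorted(set(members) - set(removed[: best_k + 1]))
    else:
        surviving = current
    return StepwiseResult(order=removed, steps=steps, best_subset=surviving)
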