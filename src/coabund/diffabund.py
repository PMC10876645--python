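"""Per-protein differential abundance, set overlaps, and sample-level PCA.

The differential test is the classic two-sample Student t (pooled variance)
on log2 ratios, with the overall fold change reported as the geometric mean
ratio between groups: ``FC = 2**(mean_b - mean_a)``.  A protein is called
*up* only when it jointly passes a fold-change gate (default > 1.2) and a
p-value gate (default < 0.05); *down* symmetrically (default < 1/1.2).  The
joint gate is deliberately used instead of a multiple-testing correction:
with isobaric-label quantitation, ratio compression biases fold changes
toward 1, and the fold-change gate acts as the practical specificity control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ingest import LOG2_RATIO, AbundanceMatrix

CALL_UP = "up"
CALL_DOWN = "down"
CALL_NS = "ns"
CALL_UNTESTABLE = "untestable"

DEFAULT_FC_UP = 1.2
DEFAULT_FC_DOWN = 1.0 / 1.2  # symmetric on the log scale; 0.83 available by override
DEFAULT_P_CUT = 0.05


@dataclass(frozen=True)
class ComparisonSpec:
    """Two disjoint groups of (genotype, timepoint) design cells."""

    group_a: frozenset
    group_b: frozenset
    label: str

    def __post_init__(self) -> None:
        if self.group_a & self.group_b:
            raise ValueError(f"comparison {self.label}: groups overlap")

    def sample_ids(self, design) -> tuple[list[str], list[str]]:
        groups = design.groups()
        a = [sid for g in sorted(self.group_a) for sid in groups.get(tuple(g), [])]
        b = [sid for g in sorted(self.group_b) for sid in groups.get(tuple(g), [])]
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"comparison {self.label}: each group needs >= 2 samples")
        return a, b


def timepoint_vs_grouped_controls(
    timepoint: str,
    control_genotype: str = "control",
    disease_genotype: str = "rNLS8",
    control_timepoints: tuple[str, ...] = ("1wk", "2wk", "4wk", "6wk"),
) -> ComparisonSpec:
    """The study's default contrast: one disease timepoint vs all controls."""
    return ComparisonSpec(
        group_a=frozenset((control_genotype, tp) for tp in control_timepoints),
        group_b=frozenset({(disease_genotype, timepoint)}),
        label=f"{disease_genotype}_{timepoint}_vs_grouped_controls",
    )


def _require_log2(matrix: AbundanceMatrix) -> None:
    if matrix.scale != LOG2_RATIO:
        raise ValueError("expected a log2-ratio matrix; call ingest.log_transform first")


def pairwise_de(
    matrix: AbundanceMatrix,
    comparison: ComparisonSpec,
    welch: bool = False,
) -> pd.DataFrame:
    """Two-sided two-sample t test per protein with geometric-mean fold change.

    Missing values are removed pairwise per protein.  Degenerate proteins
    (a group with < 2 observed values, or zero pooled variance with unequal
    means) are flagged ``untestable`` rather than raising.
    """
    _require_log2(matrix)
    ids_a, ids_b = comparison.sample_ids(matrix.design)
    A = matrix.values[ids_a].to_numpy(dtype=float)
    B = matrix.values[ids_b].to_numpy(dtype=float)

    na = (~np.isnan(A)).sum(axis=1)
    nb = (~np.isnan(B)).sum(axis=1)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ma = np.nanmean(A, axis=1)
        mb = np.nanmean(B, axis=1)
        va = np.nanvar(A, axis=1, ddof=1)
        vb = np.nanvar(B, axis=1, ddof=1)

    diff = mb - ma
    testable = (na >= 2) & (nb >= 2)
    t = np.full(len(A), np.nan)
    p = np.full(len(A), np.nan)
    df = np.full(len(A), np.nan)

    if welch:
        with np.errstate(divide="ignore", invalid="ignore"):
            se2 = va / na + vb / nb
            tt = diff / np.sqrt(se2)
            dd = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
            tt = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
            dd = (na + nb - 2).astype(float)

    zero_var = testable & np.isclose(va, 0.0) & np.isclose(vb, 0.0)
    # zero pooled variance: equal means -> t = 0; unequal means -> untestable
    tt = np.where(zero_var & np.isclose(diff, 0.0), 0.0, tt)
    untestable_var = zero_var & ~np.isclose(diff, 0.0)
    ok = testable & ~untestable_var & np.isfinite(tt)
    t[ok] = tt[ok]
    df[ok] = dd[ok]
    p[ok] = 2.0 * stats.t.sf(np.abs(tt[ok]), dd[ok])

    out = pd.DataFrame(
        {
            "comparison": comparison.label,
            "n_a": na,
            "n_b": nb,
            "log2fc": diff,
            "fold_change": np.exp2(diff),
            "t": t,
            "df": df,
            "p": p,
            "call": np.where(ok, CALL_NS, CALL_UNTESTABLE),
        },
        index=matrix.values.index,
    )
    return out


def classify_de(
    table: pd.DataFrame,
    fc_up: float = DEFAULT_FC_UP,
    fc_down: float = DEFAULT_FC_DOWN,
    p_cut: float = DEFAULT_P_CUT,
) -> pd.DataFrame:
    """Apply the joint fold-change + p-value gate, returning a copy with calls."""
    if not (0 < fc_down < 1 < fc_up):
        raise ValueError("thresholds must satisfy 0 < fc_down < 1 < fc_up")
    out = table.copy()
    testable = out["call"] != CALL_UNTESTABLE
    up = testable & (out["fold_change"] > fc_up) & (out["p"] < p_cut)
    down = testable & (out["fold_change"] < fc_down) & (out["p"] < p_cut)
    out.loc[testable, "call"] = CALL_NS
    out.loc[up, "call"] = CALL_UP
    out.loc[down, "call"] = CALL_DOWN
    return out


def protein_anova(matrix: AbundanceMatrix, grouping: dict | None = None) -> pd.DataFrame:
    """One-way fixed-effects ANOVA per protein across design groups.

    ``grouping`` maps group label -> list of sample ids; defaults to the
    design's (genotype, timepoint) cells.  Proteins with fewer than two
    groups of >= 2 observed values are flagged untestable with a reason.
    """
    _require_log2(matrix)
    if grouping is None:
        grouping = {f"{g}_{t}": ids for (g, t), ids in matrix.design.groups().items()}
    blocks = [matrix.values[ids].to_numpy(dtype=float) for ids in grouping.values()]

    nprot = matrix.n_proteins
    counts = np.column_stack([(~np.isnan(b)).sum(axis=1) for b in blocks])
    sums = np.column_stack([np.nansum(b, axis=1) for b in blocks])
    sqs = np.column_stack([np.nansum(b**2, axis=1) for b in blocks])

    usable = counts >= 2
    k = usable.sum(axis=1)
    n_tot = np.where(usable, counts, 0).sum(axis=1)
    s_tot = np.where(usable, sums, 0.0).sum(axis=1)
    sq_tot = np.where(usable, sqs, 0.0).sum(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        grand_mean = s_tot / n_tot
        group_means = np.where(usable, sums / np.maximum(counts, 1), 0.0)
        ssb = (np.where(usable, counts, 0) * (group_means - grand_mean[:, None]) ** 2).sum(axis=1)
        ssw = (sq_tot - (np.where(usable, sums, 0.0) * group_means).sum(axis=1))

    testable = k >= 2
    F = np.full(nprot, np.nan)
    p = np.full(nprot, np.nan)
    reason = np.where(testable, "", "fewer than 2 groups with >= 2 samples")
    df1 = (k - 1).astype(float)
    df2 = (n_tot - k).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ff = (ssb / df1) / (ssw / df2)
    degenerate = testable & np.isclose(ssw, 0.0)
    flat = degenerate & np.isclose(ssb, 0.0)
    reason = np.where(degenerate & ~flat, "zero within-group variance", reason)
    ok = testable & ~degenerate
    F[ok] = ff[ok]
    p[ok] = stats.f.sf(ff[ok], df1[ok], df2[ok])
    F[flat] = 0.0
    p[flat] = 1.0
    reason = np.where(flat, "", reason)

    return pd.DataFrame(
        {"F": F, "p": p, "df_between": df1, "df_within": df2,
         "untestable_reason": reason},
        index=matrix.values.index,
    )


def overlap_sets(named_sets: dict[str, set]) -> pd.DataFrame:
    """Exact exclusive-intersection cells over k named sets (sparse).

    Each element of the union lands in exactly one cell keyed by the subset
    of sets containing it; empty cells are not reported.
    """
    if len(named_sets) < 2:
        raise ValueError("need at least 2 sets")
    names = list(named_sets)
    cells: dict[tuple[str, ...], list] = {}
    for element in set().union(*named_sets.values()):
        key = tuple(nm for nm in names if element in named_sets[nm])
        cells.setdefault(key, []).append(element)
    rows = [
        {"cell": "&".join(key), "sets": key, "count": len(members),
         "members": sorted(map(str, members))}
        for key, members in cells.items()
    ]
    rows.sort(key=lambda r: (-r["count"], r["cell"]))
    return pd.DataFrame(rows, columns=["cell", "sets", "count", "members"])


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    variance_ratio: np.ndarray
    n_proteins_used: int
    n_proteins_dropped: int
    truncated: bool = False


def sample_pca(matrix: AbundanceMatrix, k: int = 5) -> PCAResult:
    """Sample-level PCA of complete-case proteins (column-mean-centred SVD)."""
    _require_log2(matrix)
    complete = matrix.values.dropna(axis=0)
    dropped = matrix.n_proteins - len(complete)
    X = complete.to_numpy(dtype=float).T  # samples x proteins
    X = X - X.mean(axis=0, keepdims=True)
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    var = S**2
    total = var.sum()
    ratio = var / total if total > 0 else np.zeros_like(var)
    rank = int((S > S[0] * 1e-12).sum()) if len(S) and S[0] > 0 else 0
    truncated = k > rank
    kk = min(k, len(S))
    scores = pd.DataFrame(
        U[:, :kk] * S[:kk],
        index=matrix.values.columns,
        columns=[f"PC{i + 1}" for i in range(kk)],
    )
    return PCAResult(scores, ratio[:kk], len(complete), dropped, truncated)
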