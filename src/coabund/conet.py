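"""Weighted co-abundance network analysis from first principles.

The chain is the standard weighted correlation network analysis recipe
applied to protein log2 ratio profiles:

1. pairwise Pearson correlation between proteins;
2. signed soft-thresholded adjacency ``a_ij = ((1 + r_ij) / 2) ** beta``;
3. soft power chosen as the smallest beta whose connectivity distribution
   approximates scale-free topology (signed R^2 of the log-log fit >= 0.85);
4. topological overlap similarity and its distance ``1 - TOM``;
5. average-linkage (UPGMA) hierarchical clustering of the TOM distance;
6. dynamic hybrid tree cut (minimum module size 20, with a PAM-like second
   stage) into modules; unassigned proteins get the reserved "grey" label;
7. module eigenproteins (first right-singular vector of the standardised
   module submatrix) and kME (correlation of each protein with each
   eigenprotein), ranking hubs by own-module kME;
8. per-module temporal profiles of member log fold changes vs a reference
   group.

The signed transform ``(1 + r) / 2`` is used rather than ``|r| ** beta`` so
anticorrelated proteins are treated as dissimilar; the absolute-value
variant is available as ``adjacency_variant="absolute"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .ingest import LOG2_RATIO, AbundanceMatrix

logger = logging.getLogger("coabund")

GREY = "grey"

# conventional module colour sequence, assigned by decreasing module size;
# labels are presentation only and never used as join keys
COLOR_SEQUENCE = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
]


@dataclass
class NetworkParams:
    """Knobs of the network construction."""

    beta: int | None = None  # None -> pick by scale-free fit
    rsq_cut: float = 0.85
    min_cluster_size: int = 20
    correlation: str = "pearson"
    adjacency_variant: str = "signed_shifted"  # or "absolute"
    tom_variant: str = "standard"
    candidate_powers: tuple[int, ...] = tuple(range(1, 21))
    deep_split: int = 2
    pam_stage: bool = True

    def __post_init__(self) -> None:
        if self.beta is not None and self.beta < 1:
            raise ValueError("beta must be >= 1")
        if not 0 < self.rsq_cut <= 1:
            raise ValueError("rsq_cut must be in (0, 1]")
        if self.min_cluster_size < 2:
            raise ValueError("min_cluster_size must be >= 2")
        if self.correlation != "pearson":
            raise ValueError("only pearson correlation is supported")
        if self.adjacency_variant not in ("signed_shifted", "absolute"):
            raise ValueError("adjacency_variant must be signed_shifted or absolute")


def correlation_matrix(matrix: AbundanceMatrix, min_shared: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation between protein profiles.

    Pairs with fewer than ``min_shared`` shared samples, and zero-variance
    proteins, yield missing correlations (logged); the adjacency step treats
    missing as correlation 0.
    """
    if matrix.scale != LOG2_RATIO:
        raise ValueError("expected a log2-ratio matrix")
    X = matrix.values.to_numpy(dtype=float)
    if not np.isnan(X).any():
        with np.errstate(invalid="ignore"):
            cor = np.corrcoef(X)
        sd = X.std(axis=1)
        zero_var = np.isclose(sd, 0.0)
        if zero_var.any():
            logger.warning("correlation_matrix: %d zero-variance proteins", int(zero_var.sum()))
            cor[zero_var, :] = np.nan
            cor[:, zero_var] = np.nan
        np.fill_diagonal(cor, 1.0)
        return pd.DataFrame(cor, index=matrix.values.index, columns=matrix.values.index)

    # pairwise-complete path
    mask = ~np.isnan(X)
    Xz = np.where(mask, X, 0.0)
    m = mask.astype(float)
    n_shared = m @ m.T
    s1 = Xz @ m.T
    s2 = (Xz**2) @ m.T
    sxy = Xz @ Xz.T
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_i = s1 / n_shared
        cov = sxy / n_shared - mean_i * mean_i.T
        var_i = s2 / n_shared - mean_i**2
        cor = cov / np.sqrt(var_i * var_i.T)
    low = n_shared < min_shared
    if low.any():
        logger.warning(
            "correlation_matrix: %d pairs with < %d shared samples set missing",
            int(low.sum() // 2), min_shared,
        )
    cor[low] = np.nan
    cor = np.clip(cor, -1.0, 1.0)
    np.fill_diagonal(cor, 1.0)
    return pd.DataFrame(cor, index=matrix.values.index, columns=matrix.values.index)


def signed_adjacency(cor: pd.DataFrame, beta: int, variant: str = "signed_shifted") -> pd.DataFrame:
    """Soft-thresholded adjacency; missing correlations count as 0."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    c = cor.to_numpy(dtype=float).copy()
    c[np.isnan(c)] = 0.0
    if variant == "signed_shifted":
        a = ((1.0 + c) / 2.0) ** beta
    elif variant == "absolute":
        a = np.abs(c) ** beta
    else:
        raise ValueError(f"unknown adjacency variant {variant!r}")
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=cor.index, columns=cor.columns)


def connectivity(adjacency: pd.DataFrame) -> pd.Series:
    """Whole-network connectivity: row sum of adjacency excluding self."""
    a = adjacency.to_numpy(dtype=float)
    k = a.sum(axis=1) - np.diag(a)
    return pd.Series(k, index=adjacency.index, name="k")


@dataclass
class ScaleFreeFit:
    signed_r2: float
    slope: float
    mean_k: float
    n_bins_used: int
    defined: bool


def scale_free_fit(k: np.ndarray | pd.Series, n_bins: int = 10) -> ScaleFreeFit:
    """Signed R^2 of the log10 p(k) vs log10 k regression over binned k.

    Connectivities are binned into ``n_bins`` equal-width bins; the log
    frequency is regressed on the log bin-mean connectivity over nonempty
    bins.  The R^2 is signed so a decreasing p(k) (scale-free-like) is
    positive.  Fewer than 3 usable bins -> fit undefined (flagged).
    """
    k = np.asarray(k, dtype=float)
    if len(k) < n_bins:
        raise ValueError("need at least n_bins connectivity values")
    mean_k = float(k.mean())
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        members = k[idx == b]
        if len(members) == 0:
            continue
        bm = members.mean()
        freq = len(members) / len(k)
        if bm > 0 and freq > 0:
            xs.append(np.log10(bm))
            ys.append(np.log10(freq))
    if len(xs) < 3 or len(set(xs)) < 2:
        return ScaleFreeFit(np.nan, np.nan, mean_k, len(xs), False)
    fit = stats.linregress(xs, ys)
    signed = -np.sign(fit.slope) * fit.rvalue**2 if fit.slope != 0 else 0.0
    return ScaleFreeFit(float(signed), float(fit.slope), mean_k, len(xs), True)


def pick_soft_threshold(
    matrix: AbundanceMatrix,
    candidate_powers: tuple[int, ...] = tuple(range(1, 21)),
    rsq_cut: float = 0.85,
    variant: str = "signed_shifted",
    n_bins: int = 10,
) -> tuple[int, pd.DataFrame, bool]:
    """Smallest candidate power whose scale-free fit reaches ``rsq_cut``.

    Returns (beta, fit table, reached).  If no candidate reaches the cut,
    the power maximising the signed R^2 among defined fits is returned with
    ``reached=False``.
    """
    cor = correlation_matrix(matrix)
    rows = []
    for power in candidate_powers:
        adj = signed_adjacency(cor, power, variant)
        fit = scale_free_fit(connectivity(adj).to_numpy(), n_bins=n_bins)
        rows.append(
            {"power": power, "signed_r2": fit.signed_r2, "slope": fit.slope,
             "mean_k": fit.mean_k, "defined": fit.defined}
        )
    table = pd.DataFrame(rows)
    defined = table[table["defined"]]
    if defined.empty:
        raise ValueError("scale-free fit undefined for every candidate power")
    reached = defined[defined["signed_r2"] >= rsq_cut]
    if not reached.empty:
        return int(reached["power"].iloc[0]), table, True
    best = defined.loc[defined["signed_r2"].idxmax(), "power"]
    logger.warning("pick_soft_threshold: rsq_cut %.2f not reached; using argmax power %d",
                   rsq_cut, int(best))
    return int(best), table, False


def topological_overlap(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap similarity.

    ``TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    ``l_ij = sum_{u != i,j} a_iu a_uj`` over off-diagonal adjacency;
    ``TOM_ii = 1``.  Distance for clustering is ``1 - TOM``.
    """
    a = adjacency.to_numpy(dtype=float).copy()
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    np.fill_diagonal(a, 0.0)
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must be in [0, 1]")
    k = a.sum(axis=1)
    shared = a @ a  # diag of a is 0, so u != i and u != j are both excluded
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + a) / (np.minimum.outer(k, k) + 1.0 - a)
    tom[~np.isfinite(tom)] = 0.0
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


@dataclass
class Dendrogram:
    """Average-linkage merge tree over proteins (scipy linkage encoding)."""

    linkage: np.ndarray
    labels: list[str]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = node.left, node.right
            bl_l = max(node.dist - left.dist, 0.0)
            bl_r = max(node.dist - right.dist, 0.0)
            return f"({walk(left)}:{bl_l:.6g},{walk(right)}:{bl_r:.6g})"

        return walk(tree) + ";"


def cluster_tree(tom_distance: pd.DataFrame) -> Dendrogram:
    """UPGMA (average linkage) clustering of the TOM distance matrix."""
    d = tom_distance.to_numpy(dtype=float)
    if np.isnan(d).any():
        raise ValueError("TOM distance contains NaN")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("distance diagonal must be zero")
    condensed = d[np.triu_indices_from(d, k=1)]
    Z = hierarchy.linkage(condensed, method="average")
    return Dendrogram(linkage=Z, labels=[str(x) for x in tom_distance.index])


@dataclass
class ModuleAssignment:
    """Protein -> module label; "grey" is the reserved unassigned label."""

    labels: pd.Series

    def modules(self) -> list[str]:
        sizes = self.labels[self.labels != GREY].value_counts()
        return list(sizes.index)

    def members(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])

    def n_assigned(self) -> int:
        return int((self.labels != GREY).sum())


def _deep_split_params(deep_split: int) -> tuple[float, float]:
    # core-scatter cap and minimum gap as fractions of the usable height range
    scatters = {0: 0.64, 1: 0.73, 2: 0.82, 3: 0.91, 4: 0.95}
    ms = scatters.get(deep_split)
    if ms is None:
        raise ValueError("deep_split must be in 0..4")
    return ms, (1.0 - ms) * 3.0 / 4.0


def dynamic_tree_cut(
    dendrogram: Dendrogram,
    tom_distance: pd.DataFrame,
    min_cluster_size: int = 20,
    deep_split: int = 2,
    pam_stage: bool = True,
    cut_height: float | None = None,
) -> ModuleAssignment:
    """Dynamic hybrid cut of the merge tree into modules.

    Stage 1 walks the merge tree bottom-up maintaining growing branches.
    When two branches meet, each is promoted to a module if it is large
    enough (``min_cluster_size``), its internal merge heights are tight
    (core scatter below a cap) and it is well separated from the join (gap
    above a floor); both caps derive from ``deep_split`` as in the published
    hybrid procedure.  Non-qualifying branches are absorbed into their
    sibling.  Stage 2 (PAM-like, default on) assigns leftover proteins to
    the nearest module by average TOM distance when they fall inside that
    module's assignment radius.  Everything else is "grey".
    """
    Z = dendrogram.linkage
    labels = dendrogram.labels
    n = len(labels)
    if min_cluster_size > n:
        return ModuleAssignment(pd.Series(GREY, index=labels, name="module"))

    heights = Z[:, 2]
    ref = float(np.quantile(heights, 0.05))
    top = float(heights.max())
    if cut_height is None:
        cut_height = ref + 0.99 * (top - ref)
    scatter_frac, gap_frac = _deep_split_params(deep_split)
    max_core_scatter = ref + scatter_frac * (cut_height - ref)
    min_gap = gap_frac * (cut_height - ref)

    class Branch:
        __slots__ = ("members", "heights", "attach", "composite")

        def __init__(self, members, hs, attach=None, composite=False):
            self.members = members
            self.heights = hs
            # height at which each member joined this branch; used to trim
            # late-attaching objects off a finalized cluster
            self.attach = attach if attach is not None else {m: 0.0 for m in members}
            self.composite = composite

    def core_scatter(branch: Branch) -> float:
        if not branch.heights:
            return 0.0
        # the "core" is the earliest-joined part of the branch: use the
        # lowest min_cluster_size-1 internal heights
        hs = sorted(branch.heights)[: max(min_cluster_size - 1, 1)]
        return float(np.mean(hs))

    def qualifies(branch: Branch, join_height: float) -> bool:
        if branch.composite or len(branch.members) < min_cluster_size:
            return False
        cs = core_scatter(branch)
        return cs <= max_core_scatter and (join_height - cs) >= min_gap

    clusters: list[list[int]] = []

    def finalize(branch: Branch, join_height: float) -> bool:
        if not qualifies(branch, join_height):
            return False
        # trim objects that chained onto the branch well above its core
        core = [m for m in branch.members if branch.attach[m] <= max_core_scatter]
        if len(core) < min_cluster_size:
            return False
        clusters.append(core)
        return True

    def merged(A: Branch, B: Branch, h: float) -> Branch:
        # the smaller branch is considered to join the larger one at h
        if len(A.members) < len(B.members):
            A, B = B, A
        attach = dict(A.attach)
        attach.update({m: float(h) for m in B.members})
        return Branch(A.members + B.members, A.heights + B.heights + [float(h)], attach)

    nodes: dict[int, Branch] = {i: Branch([i], []) for i in range(n)}
    for step, (ia, ib, h, _) in enumerate(Z):
        A = nodes.pop(int(ia))
        B = nodes.pop(int(ib))
        if h > cut_height or A.composite or B.composite:
            for X in (A, B):
                if not X.composite:
                    finalize(X, min(float(h), cut_height))
            nodes[n + step] = Branch(A.members + B.members, [], composite=True)
            continue
        qa, qb = qualifies(A, h), qualifies(B, h)
        if qa and qb:
            finalize(A, float(h))
            finalize(B, float(h))
            nodes[n + step] = Branch(A.members + B.members, [], composite=True)
        else:
            nodes[n + step] = merged(A, B, float(h))

    for branch in nodes.values():
        if not branch.composite:
            finalize(branch, cut_height)

    assignment = np.full(n, -1, dtype=int)
    for ci, members in enumerate(clusters):
        assignment[members] = ci

    if pam_stage and clusters:
        D = tom_distance.to_numpy(dtype=float)
        radii = []
        for members in clusters:
            sub = D[np.ix_(members, members)]
            # average distance of each member to the rest of its module
            avg = (sub.sum(axis=1)) / max(len(members) - 1, 1)
            radii.append(float(avg.max()))
        unassigned = np.where(assignment == -1)[0]
        for i in unassigned:
            dists = [D[i, members].mean() for members in clusters]
            best = int(np.argmin(dists))
            if dists[best] <= radii[best]:
                assignment[i] = best

    # colour labels by decreasing module size, deterministic tie-break on
    # smallest member index
    order = sorted(
        range(len(clusters)),
        key=lambda ci: (-int((assignment == ci).sum()), min(clusters[ci])),
    )
    color_of = {}
    for rank, ci in enumerate(order):
        color_of[ci] = (
            COLOR_SEQUENCE[rank] if rank < len(COLOR_SEQUENCE) else f"module{rank + 1}"
        )
    final = [color_of.get(a, GREY) if a >= 0 else GREY for a in assignment]
    return ModuleAssignment(pd.Series(final, index=labels, name="module"))


@dataclass
class EigenproteinTable:
    """Per-module summary vectors across samples."""

    vectors: pd.DataFrame  # samples x modules, unit-norm columns
    explained_variance: pd.Series  # module -> fraction in (0, 1]
    imputed_proteins: int = 0


def module_eigenproteins(
    matrix: AbundanceMatrix, assignment: ModuleAssignment
) -> EigenproteinTable:
    """First right-singular direction of each standardised module submatrix.

    Member profiles are standardised (mean 0, sd 1 across samples; missing
    values mean-imputed per protein first, flagged by count); the sign is
    fixed so the mean correlation of members with the eigenprotein is >= 0.
    """
    if matrix.scale != LOG2_RATIO:
        raise ValueError("expected a log2-ratio matrix")
    vectors = {}
    explained = {}
    imputed = 0
    for module in assignment.modules():
        members = [m for m in assignment.members(module) if m in matrix.values.index]
        sub = matrix.values.loc[members].to_numpy(dtype=float)
        if len(members) < 2:
            raise ValueError(f"module {module}: needs >= 2 proteins with profiles")
        if np.isnan(sub).any():
            imputed += int(np.isnan(sub).any(axis=1).sum())
            row_mean = np.nanmean(sub, axis=1, keepdims=True)
            sub = np.where(np.isnan(sub), row_mean, sub)
        sd = sub.std(axis=1, keepdims=True)
        if np.isclose(sd, 0.0).all():
            raise ValueError(f"module {module}: all member profiles have zero variance")
        keep = ~np.isclose(sd[:, 0], 0.0)
        Z = (sub[keep] - sub[keep].mean(axis=1, keepdims=True)) / sd[keep]
        _, S, Vt = np.linalg.svd(Z, full_matrices=False)
        v = Vt[0]
        vc = v - v.mean()
        if (Z @ vc).mean() < 0:  # mean member correlation sign
            v = -v
        vectors[module] = v
        explained[module] = float(S[0] ** 2 / (S**2).sum())
    table = pd.DataFrame(vectors, index=matrix.values.columns)
    return EigenproteinTable(
        vectors=table,
        explained_variance=pd.Series(explained, name="explained_variance"),
        imputed_proteins=imputed,
    )


def module_membership_kme(
    matrix: AbundanceMatrix, eigenproteins: EigenproteinTable
) -> pd.DataFrame:
    """kME: correlation of every protein profile with every module eigenprotein."""
    X = matrix.values.to_numpy(dtype=float)
    if np.isnan(X).any():
        row_mean = np.nanmean(X, axis=1, keepdims=True)
        X = np.where(np.isnan(X), row_mean, X)
    E = eigenproteins.vectors.to_numpy(dtype=float).T  # modules x samples
    Xc = X - X.mean(axis=1, keepdims=True)
    Ec = E - E.mean(axis=1, keepdims=True)
    xsd = Xc.std(axis=1)
    esd = Ec.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        kme = (Xc @ Ec.T / X.shape[1]) / np.outer(xsd, esd)
    kme[np.isclose(xsd, 0.0), :] = np.nan
    return pd.DataFrame(
        np.clip(kme, -1.0, 1.0), index=matrix.values.index,
        columns=eigenproteins.vectors.columns,
    )


def hub_proteins(
    kme: pd.DataFrame, assignment: ModuleAssignment, top_n: int = 6
) -> dict[str, list[str]]:
    """Top-N members of each module ranked by own-module kME descending."""
    out = {}
    for module in assignment.modules():
        members = [m for m in assignment.members(module) if m in kme.index]
        ranked = kme.loc[members, module].sort_values(ascending=False)
        out[module] = list(ranked.index[:top_n])
    return out


def module_profiles(
    matrix: AbundanceMatrix,
    assignment: ModuleAssignment,
    reference_group: tuple[str, str] | list[tuple[str, str]],
) -> pd.DataFrame:
    """Per-module distribution of member mean log2 FC per group vs reference.

    For each protein, the mean log2 ratio within each (genotype, timepoint)
    group minus its mean in the reference group(s); per module and group the
    distribution is summarised by median, quartiles, and whiskers at
    1.5 x IQR (clipped to the data range).
    """
    if matrix.scale != LOG2_RATIO:
        raise ValueError("expected a log2-ratio matrix")
    refs = [tuple(reference_group)] if isinstance(reference_group[0], str) else [
        tuple(g) for g in reference_group
    ]
    groups = matrix.design.groups()
    ref_ids = [sid for g in refs for sid in groups.get(g, [])]
    if not ref_ids:
        raise ValueError("reference group has no samples")
    ref_mean = matrix.values[ref_ids].mean(axis=1)

    rows = []
    for module in assignment.modules():
        members = [m for m in assignment.members(module) if m in matrix.values.index]
        for (genotype, timepoint), ids in groups.items():
            fc = (matrix.values.loc[members, ids].mean(axis=1) - ref_mean.loc[members]).dropna()
            if fc.empty:
                continue
            q1, med, q3 = fc.quantile([0.25, 0.5, 0.75])
            iqr = q3 - q1
            lo = fc[fc >= q1 - 1.5 * iqr].min()
            hi = fc[fc <= q3 + 1.5 * iqr].max()
            rows.append(
                {"module": module, "genotype": genotype, "timepoint": timepoint,
                 "n_proteins": len(fc), "median": med, "q1": q1, "q3": q3,
                 "whisker_low": lo, "whisker_high": hi, "mean": fc.mean()}
            )
    return pd.DataFrame(rows)
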