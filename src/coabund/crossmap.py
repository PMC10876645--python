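"""Cross-dataset meta-analysis over shared gene identifiers.

Two independent studies (e.g. a mouse proteome and a human post-mortem
proteome or transcriptome) are joined by gene symbol (case-insensitive by
default, so mouse ``Stmn2`` matches human ``STMN2``; an explicit mapping
table overrides for non-trivial orthology).  On the joined table the module
supports: exclusive intersections of altered-gene sets, direction-of-change
concordance, and module-module association between two clusterings via
Fisher exact tests with Holm correction (pairs flagged at adjusted
p < 0.001).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffabund import overlap_sets
from .enrich import adjust_pvalues

UNASSIGNED = "unassigned"


@dataclass
class DatasetSummary:
    """Per-gene log fold changes, significance calls and optional cluster labels."""

    dataset_id: str
    table: pd.DataFrame  # columns: gene_symbol, log_fc, call, optionally cluster

    def __post_init__(self) -> None:
        required = {"gene_symbol", "log_fc", "call"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"dataset {self.dataset_id}: missing columns {sorted(missing)}")
        if (self.table["gene_symbol"].astype(str).str.len() == 0).any():
            raise ValueError(f"dataset {self.dataset_id}: empty gene symbols")
        bad = set(self.table["call"].unique()) - {"up", "down", "ns", "absent"}
        if bad:
            raise ValueError(f"dataset {self.dataset_id}: unknown calls {sorted(bad)}")

    @classmethod
    def from_tsv(cls, dataset_id: str, path) -> "DatasetSummary":
        return cls(dataset_id, pd.read_csv(path, sep="\t"))


def harmonize_identifiers(
    a: DatasetSummary,
    b: DatasetSummary,
    mapping: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join two datasets over shared gene symbols.

    Default join is case-insensitive on the symbol; an explicit ``mapping``
    table (columns symbol_a, symbol_b) overrides.  One-to-many collisions
    keep all pairs and are flagged; joined/unjoined counts are attached as
    frame attrs.
    """
    ta = a.table.copy()
    tb = b.table.copy()
    if mapping is not None:
        ta["_key"] = ta["gene_symbol"].astype(str)
        tb["_key"] = tb["gene_symbol"].astype(str)
        mp = mapping.rename(columns={"symbol_a": "_key", "symbol_b": "_key_b"})
        ta = ta.merge(mp, on="_key", how="inner").drop(columns=["_key"]).rename(
            columns={"_key_b": "_key"}
        )
    else:
        ta["_key"] = ta["gene_symbol"].astype(str).str.upper()
        tb["_key"] = tb["gene_symbol"].astype(str).str.upper()

    joined = ta.merge(tb, on="_key", suffixes=(f"_{a.dataset_id}", f"_{b.dataset_id}"))
    collisions = joined["_key"].duplicated(keep=False)
    joined["collision"] = collisions
    joined = joined.rename(columns={"_key": "shared_symbol"})
    joined.attrs["n_joined"] = joined["shared_symbol"].nunique()
    joined.attrs["n_unjoined_a"] = int((~ta["_key"].isin(tb["_key"])).sum())
    joined.attrs["n_unjoined_b"] = int((~tb["_key"].isin(ta["_key"])).sum())
    return joined


def intersect_alterations(datasets: list[tuple[str, set]]) -> pd.DataFrame:
    """Exclusive-intersection counts of altered-gene sets across datasets."""
    if len(datasets) < 2:
        raise ValueError("need at least 2 datasets")
    return overlap_sets({label: set(genes) for label, genes in datasets})


def direction_concordance(
    joined: pd.DataFrame, suffix_a: str, suffix_b: str
) -> pd.DataFrame:
    """Per-gene direction category and summary fractions for a joined table.

    A gene is ``concordant-up``/``concordant-down`` when both datasets call
    it significantly in the same direction, ``discordant`` when directions
    oppose, ``one-sided`` when only one dataset calls it (the other is
    unchanged or absent).
    """
    if joined.empty:
        raise ValueError("joined table is empty")
    ca = joined[f"call_{suffix_a}"].astype(str)
    cb = joined[f"call_{suffix_b}"].astype(str)
    sig_a = ca.isin(["up", "down"])
    sig_b = cb.isin(["up", "down"])
    cat = pd.Series("unchanged", index=joined.index)
    cat[sig_a & sig_b & (ca == cb)] = "concordant-" + ca[sig_a & sig_b & (ca == cb)]
    cat[sig_a & sig_b & (ca != cb)] = "discordant"
    cat[sig_a ^ sig_b] = "one-sided"
    out = joined[["shared_symbol"]].copy()
    out["category"] = cat
    shared_calls = int((sig_a & sig_b).sum())
    out.attrs["fractions"] = (cat.value_counts() / len(cat)).to_dict()
    out.attrs["n_shared_calls"] = shared_calls
    concordant = cat.str.startswith("concordant")
    out.attrs["concordance_among_shared"] = (
        float(concordant.sum() / shared_calls) if shared_calls else np.nan
    )
    return out


def module_module_association(
    assign_a: pd.Series,
    assign_b: pd.Series,
    universe: set | None = None,
    alpha: float = 0.001,
    include_unassigned: bool = False,
    similarity_denominator: str = "min",
) -> pd.DataFrame:
    """Fisher association between two clusterings over a shared universe.

    For every cluster pair (X, Y) the 2x2 table [in X & Y, X only, Y only,
    neither] over the universe is tested two-sided; Holm adjustment is
    applied across all tested pairs (by default excluding the "unassigned"
    label from testing while keeping it in the tables); pairs with adjusted
    p < ``alpha`` are flagged.  Percent similarity defaults to
    ``overlap / min(|X|, |Y|) * 100``.
    """
    if universe is None:
        universe = set(assign_a.index) & set(assign_b.index)
    universe = sorted(universe)
    if not universe:
        raise ValueError("empty gene universe")
    la = assign_a.reindex(universe).fillna(UNASSIGNED).astype(str)
    lb = assign_b.reindex(universe).fillna(UNASSIGNED).astype(str)
    n = len(universe)

    clusters_a = sorted(la.unique())
    clusters_b = sorted(lb.unique())
    rows = []
    for x, y in itertools.product(clusters_a, clusters_b):
        in_x = la == x
        in_y = lb == y
        both = int((in_x & in_y).sum())
        nx, ny = int(in_x.sum()), int(in_y.sum())
        table = np.array([[both, nx - both], [ny - both, n - nx - ny + both]])
        degenerate = nx in (0, n) or ny in (0, n)
        p = 1.0 if degenerate else float(stats.fisher_exact(table, "two-sided")[1])
        denom = {"min": min(nx, ny), "a": nx, "jaccard": nx + ny - both}[similarity_denominator]
        rows.append(
            {"cluster_a": x, "cluster_b": y, "overlap": both, "size_a": nx,
             "size_b": ny, "percent_similarity": 100.0 * both / denom if denom else np.nan,
             "p": p, "degenerate": degenerate}
        )
    out = pd.DataFrame(rows)
    tested = out.index if include_unassigned else out.index[
        (out["cluster_a"] != UNASSIGNED) & (out["cluster_b"] != UNASSIGNED)
    ]
    out["p_adj"] = np.nan
    if len(tested):
        out.loc[tested, "p_adj"] = adjust_pvalues(out.loc[tested, "p"].to_numpy(), "holm")
    out["significant"] = out["p_adj"] < alpha
    return out
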