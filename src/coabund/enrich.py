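"""Marker-set and annotation-set enrichment for module protein lists.

Cell-type style enrichment follows the observed/expected convention: with a
background of N proteins, a module of m, a marker set of K (restricted to the
background) and an overlap of x, the enrichment ratio is ``x*N / (m*K)`` and
significance comes from a two-sided Fisher exact test on the 2x2 table.
Generic over-representation (ORA) against user-supplied GMT gene sets uses
the upper-tail hypergeometric test with Benjamini-Hochberg adjustment.

The background is always the explicit user-supplied list (e.g. the proteins
assigned to any module), never the annotation universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("coabund")


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    members: frozenset

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.set_id}: empty member list")


def read_gmt(path) -> dict[str, GeneSet]:
    """Read tab-delimited GMT (set_id, description, members...)."""
    sets: dict[str, GeneSet] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT rows need id, description, >=1 member")
            sid = fields[0]
            if sid in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set id {sid}")
            sets[sid] = GeneSet(sid, fields[1], frozenset(m for m in fields[2:] if m))
    return sets


def write_gmt(sets: dict[str, GeneSet], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets.values():
            fh.write("\t".join([s.set_id, s.description, *sorted(s.members)]) + "\n")


def restrict_to_background(sets: dict[str, GeneSet], background: set) -> dict[str, GeneSet]:
    """Intersect every set with the background; drop (and log) emptied sets."""
    if not background:
        raise ValueError("background must be nonempty")
    out: dict[str, GeneSet] = {}
    for sid, s in sets.items():
        kept = s.members & frozenset(background)
        if kept:
            out[sid] = GeneSet(sid, s.description, kept)
            logger.info("restrict_to_background: %s retained %d/%d", sid, len(kept), len(s.members))
        else:
            logger.warning("restrict_to_background: %s dropped (no members in background)", sid)
    return out


@dataclass(frozen=True)
class ContingencyTable:
    x: int  # overlap
    m: int  # module size
    K: int  # marker-set size within background
    N: int  # background size

    def __post_init__(self) -> None:
        if min(self.x, self.m, self.K, self.N) < 0:
            raise ValueError("contingency counts must be >= 0")
        if self.x > min(self.m, self.K) or max(self.m, self.K) > self.N:
            raise ValueError(f"inconsistent contingency table {self}")

    def as_2x2(self) -> np.ndarray:
        return np.array(
            [[self.x, self.m - self.x],
             [self.K - self.x, self.N - self.m - self.K + self.x]]
        )


@dataclass
class EnrichmentRecord:
    module: str
    set_id: str
    table: ContingencyTable
    enrichment_ratio: float
    odds_ratio: float
    p: float
    p_adj: float | None = None

    @property
    def direction(self) -> str:
        if np.isnan(self.enrichment_ratio):
            return "undefined"
        return "enriched" if self.enrichment_ratio >= 1.0 else "depleted"


def fisher_enrichment(
    module_members: set, marker_set: set, background: set,
    module: str = "module", set_id: str = "set",
) -> EnrichmentRecord:
    """Two-sided Fisher exact test for module x marker overlap.

    The two-sided p sums hypergeometric outcomes whose probability does not
    exceed that of the observed table (probability-mass rule).
    """
    bg = frozenset(background)
    mod = frozenset(module_members) & bg
    mark = frozenset(marker_set) & bg
    if len(mod) != len(frozenset(module_members)) or len(mark) != len(frozenset(marker_set)):
        raise ValueError("module and marker set must be subsets of the background")
    table = ContingencyTable(x=len(mod & mark), m=len(mod), K=len(mark), N=len(bg))
    if table.m * table.K == 0:
        return EnrichmentRecord(module, set_id, table, np.nan, np.nan, 1.0)
    ratio = table.x * table.N / (table.m * table.K)
    t = table.as_2x2()
    odds = stats.contingency.odds_ratio(t, kind="sample").statistic if t.min() >= 0 else np.nan
    p = float(stats.fisher_exact(t, alternative="two-sided")[1])
    return EnrichmentRecord(module, set_id, table, float(ratio), float(odds), min(p, 1.0))


def ora(
    query_set: set,
    annotation_sets: dict[str, GeneSet],
    background: set,
    query_label: str = "query",
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation with BH adjustment.

    ``p = P(X >= x)`` for overlap x between the query and each annotation
    set, both restricted to the background; results sorted by p.
    """
    bg = frozenset(background)
    query = frozenset(query_set) & bg
    if len(query) != len(frozenset(query_set)):
        raise ValueError("query must be a subset of the background")
    restricted = restrict_to_background(annotation_sets, bg)
    rows = []
    for sid, s in restricted.items():
        x = len(query & s.members)
        table = ContingencyTable(x=x, m=len(query), K=len(s.members), N=len(bg))
        # P(X >= x) = survival function at x-1
        p = float(stats.hypergeom.sf(x - 1, table.N, table.K, table.m))
        ratio = (
            x * table.N / (table.m * table.K) if table.m * table.K > 0 else np.nan
        )
        rows.append(
            {"query": query_label, "set_id": sid, "x": x, "m": table.m,
             "K": table.K, "N": table.N, "enrichment_ratio": ratio, "p": min(p, 1.0)}
        )
    if not rows:
        return pd.DataFrame(
            columns=["query", "set_id", "x", "m", "K", "N", "enrichment_ratio", "p", "p_adj"]
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = adjust_pvalues(out["p"].to_numpy(), method="bh")
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def adjust_pvalues(pvalues, method: str = "bh") -> np.ndarray:
    """Holm (step-down FWER) or Benjamini-Hochberg (step-up FDR) adjustment.

    Input order is preserved in the output; values are capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    key = {"holm": "holm", "bh": "fdr_bh"}.get(method)
    if key is None:
        raise ValueError("method must be 'holm' or 'bh'")
    return multipletests(p, method=key)[1]


def enrichment_records_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    rows = [
        {"module": r.module, "set_id": r.set_id, "x": r.table.x, "m": r.table.m,
         "K": r.table.K, "N": r.table.N, "enrichment_ratio": r.enrichment_ratio,
         "odds_ratio": r.odds_ratio, "p": r.p, "p_adj": r.p_adj,
         "direction": r.direction}
        for r in records
    ]
    return pd.DataFrame(rows)


def module_marker_enrichment(
    assignment_labels: pd.Series,
    marker_sets: dict[str, GeneSet],
    background: set | None = None,
    unassigned_label: str = "grey",
) -> pd.DataFrame:
    """Fisher enrichment of every module against every marker set.

    Default background = all proteins assigned to any module; marker sets
    are first restricted to that background.  p-values are BH-adjusted
    across the whole module x set family.
    """
    assigned = assignment_labels[assignment_labels != unassigned_label]
    bg = set(background) if background is not None else set(assigned.index)
    restricted = restrict_to_background(marker_sets, bg)
    records = []
    for module in assigned.unique():
        members = set(assigned.index[assigned == module]) & bg
        for sid, s in restricted.items():
            records.append(
                fisher_enrichment(members, set(s.members), bg, module=module, set_id=sid)
            )
    frame = enrichment_records_frame(records)
    if not frame.empty:
        frame["p_adj"] = adjust_pvalues(frame["p"].to_numpy(), method="bh")
    return frame
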