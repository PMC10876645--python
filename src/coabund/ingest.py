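"""Reading, normalising, merging and filtering multiplexed abundance data.

Quantitation in an isobaric-label (TMT) experiment is relative within one
mass-spec run (a *plex*).  Each plex carries one reference channel loaded with
a pooled sample; expressing every biological channel as a ratio to that
reference puts all plexes on a common scale.  This module turns per-plex
channel intensity tables into the pipeline's central object, the
:class:`AbundanceMatrix` (proteins x biological samples of ratios, linear or
log2), carrying its :class:`StudyDesign` alongside.

Missing data stay explicit (``NaN``); no imputation happens here.  Every
filtering step reports how many proteins it dropped -- silent data loss is
forbidden by contract.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("coabund")

LINEAR_RATIO = "linear_ratio"
LOG2_RATIO = "log2_ratio"


class SchemaError(ValueError):
    """Malformed input file or design table."""


class DesignError(ValueError):
    """Inconsistent study design (duplicate channels, duplicate samples...)."""


class TransformError(ValueError):
    """Value domain violation during a numeric transform."""


@dataclass(frozen=True)
class SampleMeta:
    """One biological sample: where it sits (plex, channel) and what it is."""

    sample_id: str
    genotype: str
    timepoint: str
    plex: str
    channel: str

    @property
    def group(self) -> tuple[str, str]:
        return (self.genotype, self.timepoint)


@dataclass
class StudyDesign:
    """Assignment of biological samples to (plex, channel) slots.

    Every plex has exactly one reference channel (the pooled sample); the
    reference is not a biological sample and never appears in ``samples``.
    """

    samples: list[SampleMeta]
    reference_channel_by_plex: dict[str, str]

    def __post_init__(self) -> None:
        seen_slots: set[tuple[str, str]] = set()
        seen_ids: set[str] = set()
        for s in self.samples:
            slot = (s.plex, s.channel)
            if slot in seen_slots:
                raise DesignError(f"duplicate channel assignment: plex {s.plex} channel {s.channel}")
            if s.sample_id in seen_ids:
                raise DesignError(f"duplicate sample_id: {s.sample_id}")
            if s.plex not in self.reference_channel_by_plex:
                raise DesignError(f"sample {s.sample_id} in plex {s.plex} with no reference channel")
            if s.channel == self.reference_channel_by_plex[s.plex]:
                raise DesignError(
                    f"sample {s.sample_id} assigned to the reference channel of plex {s.plex}"
                )
            seen_slots.add(slot)
            seen_ids.add(s.sample_id)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def samples_in_plex(self, plex: str) -> list[SampleMeta]:
        return [s for s in self.samples if s.plex == plex]

    def groups(self) -> dict[tuple[str, str], list[str]]:
        """Mapping (genotype, timepoint) -> sample ids, in design order."""
        out: dict[tuple[str, str], list[str]] = {}
        for s in self.samples:
            out.setdefault(s.group, []).append(s.sample_id)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": s.sample_id,
                "plex": s.plex,
                "channel": s.channel,
                "genotype": s.genotype,
                "timepoint": s.timepoint,
            }
            for s in self.samples
        ]
        return pd.DataFrame(rows, columns=["sample_id", "plex", "channel", "genotype", "timepoint"])

    def to_tsv(self, path) -> None:
        frame = self.to_frame()
        ref = pd.DataFrame(
            {
                "sample_id": [f"reference_{p}" for p in self.reference_channel_by_plex],
                "plex": list(self.reference_channel_by_plex),
                "channel": list(self.reference_channel_by_plex.values()),
                "genotype": "reference",
                "timepoint": "pooled",
            }
        )
        pd.concat([frame, ref], ignore_index=True).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "StudyDesign":
        rows = read_strict_tsv(path)
        header, body = rows[0], rows[1:]
        expected = ["sample_id", "plex", "channel", "genotype", "timepoint"]
        if header != expected:
            raise SchemaError(f"design header must be {expected}, got {header}")
        samples, refs = [], {}
        for r in body:
            rec = dict(zip(header, r))
            if rec["genotype"] == "reference":
                if rec["plex"] in refs:
                    raise DesignError(f"plex {rec['plex']} has two reference channels")
                refs[rec["plex"]] = rec["channel"]
            else:
                samples.append(
                    SampleMeta(rec["sample_id"], rec["genotype"], rec["timepoint"], rec["plex"], rec["channel"])
                )
        return cls(samples=samples, reference_channel_by_plex=refs)


@dataclass
class PlexIntensities:
    """Linear channel intensities for one plex (rows proteins, cols channels)."""

    plex: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise SchemaError(f"plex {self.plex}: duplicate protein_ids")
        if (self.values.to_numpy(dtype=float) < 0).any():
            raise SchemaError(f"plex {self.plex}: negative intensities")

    def to_tsv(self, path) -> None:
        write_matrix_tsv(self.values, path)

    @classmethod
    def from_tsv(cls, plex: str, path) -> "PlexIntensities":
        return cls(plex=plex, values=read_matrix_tsv(path))


@dataclass
class AbundanceMatrix:
    """Proteins x biological samples of ratio-to-reference values.

    ``scale`` says whether ``values`` holds linear ratios or log2 ratios.
    Missing entries are ``NaN`` and are permitted everywhere downstream ops
    declare their own missing policy.
    """

    values: pd.DataFrame
    design: StudyDesign
    scale: str = LINEAR_RATIO

    def __post_init__(self) -> None:
        if self.scale not in (LINEAR_RATIO, LOG2_RATIO):
            raise SchemaError(f"unknown scale {self.scale!r}")
        if list(self.values.columns) != self.design.sample_ids:
            missing = set(self.design.sample_ids) ^ set(self.values.columns)
            if missing:
                raise SchemaError(f"matrix columns and design samples differ: {sorted(missing)[:5]}")
            self.values = self.values[self.design.sample_ids]
        if self.scale == LINEAR_RATIO:
            vals = self.values.to_numpy(dtype=float)
            if np.nanmin(vals, initial=np.inf) <= 0:
                raise SchemaError("linear ratios must be positive where present")

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    def to_tsv(self, path) -> None:
        write_matrix_tsv(self.values, path)

    @classmethod
    def from_tsv(cls, path, design: StudyDesign, scale: str = LINEAR_RATIO) -> "AbundanceMatrix":
        return cls(values=read_matrix_tsv(path), design=design, scale=scale)


# ---------------------------------------------------------------------------
# strict TSV IO (rejects ragged rows; empty cell = missing)

def read_strict_tsv(path) -> list[list[str]]:
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise SchemaError(f"{path}: empty file")
    width = len(rows[0])
    for i, row in enumerate(rows):
        if len(row) != width:
            raise SchemaError(f"{path}: ragged row {i + 1} ({len(row)} fields, expected {width})")
    return rows


def read_matrix_tsv(path) -> pd.DataFrame:
    rows = read_strict_tsv(path)
    header = rows[0]
    if not header or header[0] != "protein_id":
        raise SchemaError(f"{path}: first column must be 'protein_id'")
    index, data = [], []
    for row in rows[1:]:
        index.append(row[0])
        data.append([float(c) if c != "" else np.nan for c in row[1:]])
    return pd.DataFrame(data, index=pd.Index(index, name="protein_id"), columns=header[1:])


def write_matrix_tsv(frame: pd.DataFrame, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein_id\t" + "\t".join(map(str, frame.columns)) + "\n")
        for pid, row in zip(frame.index, frame.to_numpy(dtype=float)):
            cells = ["" if np.isnan(v) else format(v, ".12g") for v in row]
            fh.write(str(pid) + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# operations

def reference_ratios(plex: PlexIntensities, reference_channel: str) -> pd.DataFrame:
    """Ratio of every biological channel to the plex's reference channel.

    Proteins with zero or missing reference intensity cannot be expressed as
    a ratio; they are dropped with a logged count, never silently.
    """
    if reference_channel not in plex.values.columns:
        raise SchemaError(f"plex {plex.plex}: reference channel {reference_channel} absent")
    ref = plex.values[reference_channel]
    bad = ~(ref > 0)
    if bad.any():
        logger.warning(
            "plex %s: dropping %d/%d proteins with zero or missing reference intensity",
            plex.plex, int(bad.sum()), len(ref),
        )
    kept = plex.values.loc[~bad]
    ratios = kept.drop(columns=[reference_channel]).div(kept[reference_channel], axis=0)
    return ratios


def merge_plexes(ratio_tables: dict[str, pd.DataFrame], design: StudyDesign) -> AbundanceMatrix:
    """Merge per-plex ratio tables into one matrix over the union of proteins.

    Channel columns are renamed to sample ids via the design; proteins missing
    from a plex get NaN in that plex's sample columns.
    """
    pieces = []
    claimed: set[str] = set()
    for plex_id, table in ratio_tables.items():
        plex_samples = design.samples_in_plex(plex_id)
        chan_to_sample = {s.channel: s.sample_id for s in plex_samples}
        unknown = set(table.columns) - set(chan_to_sample)
        if unknown:
            raise DesignError(f"plex {plex_id}: channels {sorted(unknown)} not in design")
        renamed = table.rename(columns=chan_to_sample)
        dup = claimed & set(renamed.columns)
        if dup:
            raise DesignError(f"sample(s) {sorted(dup)} claimed by more than one plex")
        claimed |= set(renamed.columns)
        pieces.append(renamed)
    merged = pd.concat(pieces, axis=1)
    absent = [s for s in design.sample_ids if s not in merged.columns]
    if absent:
        raise DesignError(f"design samples with no data: {absent[:5]}")
    merged = merged[design.sample_ids].sort_index()
    return AbundanceMatrix(values=merged, design=design, scale=LINEAR_RATIO)


def filter_missing(matrix: AbundanceMatrix, max_missing_fraction: float = 0.0) -> AbundanceMatrix:
    """Keep proteins whose missing-sample fraction is <= threshold (inclusive)."""
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    frac = matrix.values.isna().mean(axis=1)
    keep = frac <= max_missing_fraction
    logger.info(
        "filter_missing(<=%.3g): retained %d, dropped %d proteins",
        max_missing_fraction, int(keep.sum()), int((~keep).sum()),
    )
    return AbundanceMatrix(values=matrix.values.loc[keep], design=matrix.design, scale=matrix.scale)


def log_transform(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """log2 of linear ratios; missing entries preserved."""
    if matrix.scale != LINEAR_RATIO:
        raise TransformError("matrix is not on the linear ratio scale")
    vals = matrix.values.to_numpy(dtype=float)
    bad = (vals <= 0) & ~np.isnan(vals)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise TransformError(
            f"nonpositive ratio at protein {matrix.values.index[i]}, sample {matrix.values.columns[j]}"
        )
    out = pd.DataFrame(np.log2(vals), index=matrix.values.index, columns=matrix.values.columns)
    return AbundanceMatrix(values=out, design=matrix.design, scale=LOG2_RATIO)


def unlog_transform(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Inverse of :func:`log_transform` (2**x), for round-trips."""
    if matrix.scale != LOG2_RATIO:
        raise TransformError("matrix is not on the log2 ratio scale")
    out = pd.DataFrame(
        np.exp2(matrix.values.to_numpy(dtype=float)),
        index=matrix.values.index, columns=matrix.values.columns,
    )
    return AbundanceMatrix(values=out, design=matrix.design, scale=LINEAR_RATIO)
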