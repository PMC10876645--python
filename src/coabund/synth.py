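"""Synthetic longitudinal multiplexed proteomics with known planted structure.

The generator emulates a 5-plex TMT10 longitudinal design: 45 biological
samples (5 mice x 4 control timepoints + 5 mice x 5 disease timepoints,
including a recovery arm), one pooled-reference channel per plex, planted
co-abundance modules with genotype x time profiles, protein-level plex batch
effects, log-normal measurement noise and protein-by-plex missingness.

Model for protein ``i`` in sample ``s`` (log2 scale)::

    y_is = b_i + shift_{tmpl(i)}(genotype_s, timepoint_s)
               + l_i * sigma_m * z_m(s)          # shared module factor
               + c_i * g(s)                      # weak background factor
               + pi_{i, plex(s)}                 # residual batch effect
               + eps_is,     eps ~ N(0, noise_sd)

Loadings ``l_i ~ U(0.5, 1)``; the factor scale ``sigma_m`` is chosen so the
expected within-module Pearson correlation of log ratios hits the configured
target.  The reference channel of each plex is the noiseless pooled mean of
the control-condition expectations, so with zero noise and no planted effects
every ratio is exactly 1.  All randomness flows from one seed through named
sub-streams, so edits to one part of the configuration do not perturb the
draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ingest import DesignError, PlexIntensities, SampleMeta, StudyDesign

BACKGROUND = "background"

TMT10_CHANNELS = ["126", "127N", "127C", "128N", "128C", "129N", "129C", "130N", "130C", "131"]

CONTROL_TIMEPOINTS = ["1wk", "2wk", "4wk", "6wk"]
DISEASE_TIMEPOINTS = ["1wk", "2wk", "4wk", "6wk", "rec"]
CONTROL = "control"
DISEASE = "rNLS8"


class SizingError(DesignError):
    """Design does not fit into the requested plex capacity."""


@dataclass(frozen=True)
class ProfileTemplate:
    """Deterministic planted log2 offsets per (genotype, timepoint) cell."""

    template_id: str
    shift: dict[tuple[str, str], float]

    def value(self, genotype: str, timepoint: str) -> float:
        key = (genotype, timepoint)
        if key not in self.shift:
            raise KeyError(f"template {self.template_id}: undefined cell {key}")
        return self.shift[key]


def template_value(template: ProfileTemplate, genotype: str, timepoint: str) -> float:
    """Planted log2 offset of a template at one design cell."""
    return template.value(genotype, timepoint)


def builtin_templates(effect_size_log2: float) -> dict[str, ProfileTemplate]:
    """Archetype genotype x time profiles scaled to one effect size.

    The disease-only archetypes are flat (offset 0) in controls; the
    age-associated archetype drifts in both genotypes, emulating modules that
    change with age rather than with disease.
    """
    e = effect_size_log2

    def build(tid, disease_by_tp, control_by_tp=None):
        shift = {}
        for tp in CONTROL_TIMEPOINTS:
            shift[(CONTROL, tp)] = 0.0 if control_by_tp is None else control_by_tp[tp]
        for tp in DISEASE_TIMEPOINTS:
            shift[(DISEASE, tp)] = disease_by_tp[tp]
        return ProfileTemplate(tid, shift)

    age_ramp = {"1wk": 0.0, "2wk": e / 3, "4wk": 2 * e / 3, "6wk": e}
    templates = [
        build("transient-early-up",
              {"1wk": e, "2wk": e, "4wk": 0.5 * e, "6wk": 0.0, "rec": 0.0}),
        build("progressive-down-partial-recovery",
              {"1wk": 0.0, "2wk": -0.5 * e, "4wk": -e, "6wk": -e, "rec": -0.4 * e}),
        build("late-up-persisting",
              {"1wk": 0.0, "2wk": 0.0, "4wk": 0.3 * e, "6wk": e, "rec": e}),
        build("early-maintained-up",
              {"1wk": 0.0, "2wk": e, "4wk": e, "6wk": e, "rec": 0.0}),
        build("late-up-partial-reversal",
              {"1wk": 0.0, "2wk": 0.0, "4wk": 0.5 * e, "6wk": e, "rec": 0.4 * e}),
        build("age-linear-up", {**age_ramp, "rec": e}, control_by_tp=age_ramp),
        build("null", {tp: 0.0 for tp in DISEASE_TIMEPOINTS}),
    ]
    return {t.template_id: t for t in templates}


DEFAULT_MODULE_SPEC = [
    ("mod1", 150, "progressive-down-partial-recovery"),
    ("mod2", 120, "early-maintained-up"),
    ("mod3", 100, "late-up-partial-reversal"),
    ("mod4", 80, "late-up-persisting"),
    ("mod5", 50, "transient-early-up"),
    ("mod6", 30, "age-linear-up"),
]


def generate_design(
    n_per_group: int = 5,
    control_timepoints: list[str] = CONTROL_TIMEPOINTS,
    disease_timepoints: list[str] = DISEASE_TIMEPOINTS,
    n_plexes: int = 5,
    channels_per_plex: int = 10,
    reference_channel: str = "131",
    seed: int = 0,
    control_genotype: str = CONTROL,
    disease_genotype: str = DISEASE,
) -> StudyDesign:
    """Randomised assignment of biological samples to (plex, channel) slots.

    One channel per plex is reserved for the pooled reference; the remaining
    slots receive the biological samples in a seed-determined shuffle.
    """
    if channels_per_plex == 10:
        channels = list(TMT10_CHANNELS)
    else:
        channels = [f"c{i}" for i in range(1, channels_per_plex + 1)]
    if reference_channel not in channels:
        raise DesignError(f"reference channel {reference_channel!r} not among plex channels")

    groups = [(control_genotype, tp) for tp in control_timepoints]
    groups += [(disease_genotype, tp) for tp in disease_timepoints]
    total = n_per_group * len(groups)
    capacity = n_plexes * (channels_per_plex - 1)
    if total > capacity:
        raise SizingError(
            f"{total} biological samples exceed capacity {capacity} "
            f"({n_plexes} plexes x {channels_per_plex - 1} non-reference channels)"
        )

    slots = [
        (f"plex{p + 1}", ch)
        for p in range(n_plexes)
        for ch in channels
        if ch != reference_channel
    ]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(slots))[:total]

    samples = []
    i = 0
    for genotype, tp in groups:
        for rep in range(1, n_per_group + 1):
            plex, ch = slots[order[i]]
            samples.append(
                SampleMeta(f"{genotype}_{tp}_{rep}", genotype, tp, plex, ch)
            )
            i += 1
    refs = {f"plex{p + 1}": reference_channel for p in range(n_plexes)}
    return StudyDesign(samples=samples, reference_channel_by_plex=refs)


@dataclass
class SynthConfig:
    """All knobs of the simulator; defaults are the study-like conditions."""

    n_proteins: int = 2000
    module_spec: list[tuple[str, int, str]] = field(
        default_factory=lambda: list(DEFAULT_MODULE_SPEC)
    )
    module_correlation: float = 0.7
    module_factor_sd: float | None = None  # explicit latent-factor sd override
    background_correlation: float = 0.0
    noise_sd: float = 0.3
    plex_effect_sd: float = 0.1
    missing_plex_prob: float = 0.0
    effect_size_log2: float = 0.585
    negative_loading_fraction: float = 0.0
    noisy_reference: bool = False
    design: StudyDesign | None = None
    seed: int = 42

    def __post_init__(self) -> None:
        sizes = [size for _, size, _ in self.module_spec]
        if any(s < 1 for s in sizes):
            raise ValueError("module sizes must be >= 1")
        if sum(sizes) > self.n_proteins:
            raise ValueError("sum of module sizes exceeds n_proteins")
        if len({m for m, _, _ in self.module_spec}) != len(self.module_spec):
            raise ValueError("duplicate module ids")
        if self.noise_sd < 0 or self.plex_effect_sd < 0:
            raise ValueError("noise_sd and plex_effect_sd must be >= 0")
        if not 0.0 <= self.missing_plex_prob < 1.0:
            raise ValueError("missing_plex_prob must be in [0, 1)")
        if not 0.0 <= self.module_correlation < 1.0:
            raise ValueError("module_correlation must be in [0, 1)")
        if not 0.0 <= self.background_correlation < 1.0:
            raise ValueError("background_correlation must be in [0, 1)")
        if self.design is None:
            self.design = generate_design(seed=self.seed)


@dataclass
class GroundTruth:
    """Planted structure emitted alongside the simulated data."""

    module_label_by_protein: pd.Series  # protein_id -> module id or "background"
    template_by_module: dict[str, str]
    effect_by_protein_group: pd.DataFrame  # proteins x (genotype, timepoint) planted log2 offsets

    def module_sizes(self) -> pd.Series:
        return self.module_label_by_protein.value_counts()

    def de_effect(self, timepoint: str, disease_genotype: str = DISEASE,
                  control_genotype: str = CONTROL) -> pd.Series:
        """Planted log2 effect of disease@timepoint vs grouped controls."""
        eff = self.effect_by_protein_group
        ctrl_cols = [c for c in eff.columns if c[0] == control_genotype]
        return eff[(disease_genotype, timepoint)] - eff[ctrl_cols].mean(axis=1)

    def de_status(self, timepoint: str, disease_genotype: str = DISEASE,
                  control_genotype: str = CONTROL) -> pd.Series:
        """Planted up/down/null status of disease@timepoint vs grouped controls."""
        delta = self.de_effect(timepoint, disease_genotype, control_genotype)
        status = pd.Series("null", index=delta.index)
        status[delta > 1e-12] = "up"
        status[delta < -1e-12] = "down"
        return status

    def to_tsv(self, path) -> None:
        frame = pd.DataFrame(
            {
                "protein_id": self.module_label_by_protein.index,
                "module_id": self.module_label_by_protein.values,
                "template_id": [
                    self.template_by_module.get(m, "null")
                    for m in self.module_label_by_protein.values
                ],
            }
        )
        frame.to_csv(path, sep="\t", index=False)


def _factor_scale(target_corr: float, noise_sd: float, mean_loading: float) -> float:
    """Latent-factor sd giving the target within-module correlation.

    For proteins with loading l on a unit-variance factor plus N(0, noise_sd)
    noise, corr = l^2 s^2 / (l^2 s^2 + noise_sd^2) at the mean loading.
    """
    if target_corr == 0 or noise_sd == 0:
        return 0.0
    return noise_sd / mean_loading * np.sqrt(target_corr / (1.0 - target_corr))


def simulate_dataset(config: SynthConfig) -> tuple[dict[str, PlexIntensities], GroundTruth]:
    """Simulate per-plex linear channel intensities plus the ground truth."""
    design = config.design
    assert design is not None
    templates = builtin_templates(config.effect_size_log2)
    for _, _, tid in config.module_spec:
        if tid not in templates:
            raise ValueError(f"unknown profile template {tid!r}")

    n = config.n_proteins
    protein_ids = [f"P{i:05d}" for i in range(1, n + 1)]
    samples = design.samples
    n_samples = len(samples)

    # named sub-streams: config edits to one component leave the others stable
    root = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(s)
        for name, s in zip(
            ["baseline", "loadings", "factors", "background", "plex", "noise", "missing"],
            root.spawn(7),
        )
    }

    baseline = streams["baseline"].uniform(18.0, 24.0, size=n)

    labels = np.full(n, BACKGROUND, dtype=object)
    template_by_module: dict[str, str] = {}
    pos = 0
    for mod_id, size, tid in config.module_spec:
        labels[pos:pos + size] = mod_id
        template_by_module[mod_id] = tid
        pos += size

    loadings = streams["loadings"].uniform(0.5, 1.0, size=n)
    if config.negative_loading_fraction > 0:
        flip = streams["loadings"].random(n) < config.negative_loading_fraction
        loadings[flip] *= -1.0

    if config.module_factor_sd is not None:
        sigma_m = config.module_factor_sd
    else:
        sigma_m = _factor_scale(config.module_correlation, config.noise_sd, 0.75)
    sigma_bg = _factor_scale(config.background_correlation, config.noise_sd, 1.0)

    # planted offsets per protein per group
    group_cols = sorted({s.group for s in samples})
    effect = pd.DataFrame(
        0.0, index=pd.Index(protein_ids, name="protein_id"),
        columns=pd.MultiIndex.from_tuples(group_cols, names=["genotype", "timepoint"]),
    )
    for mod_id, _, tid in config.module_spec:
        tmpl = templates[tid]
        mask = labels == mod_id
        for g in group_cols:
            effect.loc[mask, g] = tmpl.value(*g)

    # per-sample signal on log2 scale
    y = np.tile(baseline[:, None], (1, n_samples))
    sample_groups = [s.group for s in samples]
    group_pos = {g: [i for i, sg in enumerate(sample_groups) if sg == g] for g in group_cols}
    eff_vals = effect.to_numpy()
    for j, g in enumerate(group_cols):
        y[:, group_pos[g]] += eff_vals[:, [j]]

    for mod_id, _, _ in config.module_spec:
        mask = labels == mod_id
        z = streams["factors"].standard_normal(n_samples)
        y[mask, :] += np.outer(loadings[mask] * sigma_m, z)
    if sigma_bg > 0:
        g_factor = streams["background"].standard_normal(n_samples)
        y[labels == BACKGROUND, :] += np.outer(
            np.full(int((labels == BACKGROUND).sum()), sigma_bg), g_factor
        )

    plex_ids = sorted(design.reference_channel_by_plex)
    plex_offsets = {
        p: streams["plex"].normal(0.0, config.plex_effect_sd, size=n) if config.plex_effect_sd > 0
        else np.zeros(n)
        for p in plex_ids
    }
    for j, s in enumerate(samples):
        y[:, j] += plex_offsets[s.plex]

    if config.noise_sd > 0:
        y += streams["noise"].normal(0.0, config.noise_sd, size=(n, n_samples))

    # reference = pooled mean of control-condition expectations (linear scale)
    ctrl_groups = [g for g in group_cols if g[0] == CONTROL] or group_cols
    ctrl_idx = [effect.columns.get_loc(g) for g in ctrl_groups]
    ref_linear = np.exp2(baseline[:, None] + eff_vals[:, ctrl_idx]).mean(axis=1)
    if config.noisy_reference and config.noise_sd > 0:
        ref_linear = ref_linear * np.exp2(
            streams["noise"].normal(0.0, config.noise_sd, size=n)
        )

    missing = {
        p: streams["missing"].random(n) < config.missing_plex_prob
        for p in plex_ids
    }

    intensities = np.exp2(y)
    plexes: dict[str, PlexIntensities] = {}
    for p in plex_ids:
        plex_samples = design.samples_in_plex(p)
        cols = {s.channel: intensities[:, samples.index(s)] for s in plex_samples}
        cols[design.reference_channel_by_plex[p]] = ref_linear
        table = pd.DataFrame(cols, index=pd.Index(protein_ids, name="protein_id"))
        table = table.loc[~missing[p]]
        plexes[p] = PlexIntensities(plex=p, values=table)

    truth = GroundTruth(
        module_label_by_protein=pd.Series(labels, index=protein_ids, name="module_id"),
        template_by_module=template_by_module,
        effect_by_protein_group=effect,
    )
    return plexes, truth
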