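"""Simulate a 5-plex longitudinal TMT experiment with planted modules.

Builds the default study-like design (45 mice: 5 per group over 4 control
and 5 disease timepoints, TMT10 channels, pooled reference in channel 131),
simulates protein-level channel intensities, and shows the planted truth.
"""

from coabund import synth

config = synth.SynthConfig(seed=42)
plexes, truth = synth.simulate_dataset(config)

design = config.design
print(f"design: {len(design.samples)} biological samples in "
      f"{len(design.reference_channel_by_plex)} plexes "
      f"(reference channel {design.reference_channel_by_plex['plex1']})")
print(f"groups: {len(design.groups())} (genotype x timepoint), "
      f"{len(design.groups()[('control', '1wk')])} mice each")

sizes = truth.module_sizes()
print("\nplanted modules (protein counts):")
for module, template in truth.template_by_module.items():
    print(f"  {module:5s} n={sizes[module]:4d}  profile: {template}")
print(f"  background n={sizes[synth.BACKGROUND]}")

tab = plexes["plex1"].values
print(f"\nplex1 intensity table: {tab.shape[0]} proteins x {tab.shape[1]} channels, "
      f"median intensity {tab.to_numpy().mean():.3g}")
print("Each biological channel will be expressed as a ratio to the pooled")
print("reference, which puts all five plexes on one comparable scale.")
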