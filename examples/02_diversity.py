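"""Rarefied richness and evenness along a synthetic core.

Standardizes every sample to a common 300-grain count (rarefaction) so
richness is comparable despite unequal counting effort, and splits
richness into tree vs shrub/herb components.
"""

import numpy as np

from palaeoveg import GeneratorConfig, simulate_core, pielou_evenness
from palaeoveg.diversity import group_diversity, rarefied_richness

cfg = GeneratorConfig(span=700.0, seed=7)
core, truth = simulate_core(cfg)

rich = np.array([rarefied_richness(s.counts, 300) for s in core.samples])
even = np.array([pielou_evenness(s.counts) for s in core.samples])
ages = core.ages
old = ages > 350
print(f"rarefied richness E(S_300): older half median {np.median(rich[old]):.1f}, "
      f"younger half median {np.median(rich[~old]):.1f}")
print(f"Pielou evenness: record median {np.nanmedian(even):.2f}")

# standardize each group to 50 grains; samples with fewer go missing
div = group_diversity(core, n=50)
print("\nper-group richness medians (50-grain within-group standardization):")
print(f"  tree:       older half {np.nanmedian(div['tree'][old]):.1f}, "
      f"younger half {np.nanmedian(div['tree'][~old]):.1f}")
print(f"  shrub/herb: older half {np.nanmedian(div['shrub_herb'][old]):.1f}, "
      f"younger half {np.nanmedian(div['shrub_herb'][~old]):.1f}")
print(f"samples with <50 tree grains (missing tree richness): "
      f"{int(div['tree'].isna().sum())}")
print("\nTree richness falls as the cooling trend removes warm conifers;")
print("shrub/herb richness rises as meadow taxa take over.")
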