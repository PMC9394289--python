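"""Compare adjacency constructions and normalization on identical splits.

Reproduces the structure of the ablation analyses: distance-only vs
connectivity-only vs fused adjacency, with and without node-feature
normalization, all on the same seeded cross-validation folds so the
differences are attributable to the variant.
"""

import numpy as np

from crgcn import (
    ExperimentConfig,
    ModelConfig,
    SynthConfig,
    generate_trialset,
    run_ablation,
)

rng = np.random.default_rng(0)
subjects = [
    generate_trialset(
        SynthConfig(n_trials_per_subject=12, seed=40 + si,
                    band_effect={"gamma": (1.0, 1.35)},
                    channel_scale_spread=1.0, spatial_corr_scale=2.0),
        rng.permutation(np.arange(12) % 2),
        subject_id=f"s{si}",
    )
    for si in range(2)
]

cfg = ExperimentConfig(model=ModelConfig(max_epochs=60, seed=0), seed=2)
variants = [
    {"adjacency": "distance"},
    {"adjacency": "cc", "lam": 0.3},
    {"adjacency": "fused", "lam": 0.3},
    {"adjacency": "fused", "lam": 0.3, "normalize": False},
]
reports, table = run_ablation(subjects, cfg, variants=variants)
print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print("-> normalization absorbs the per-channel scale confound (last row); "
      "adjacency variants are close on any single seed — the fused-vs-"
      "distance direction emerges in multi-seed medians")
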