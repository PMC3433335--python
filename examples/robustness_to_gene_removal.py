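"""How stable is a score profile when the HYP loses downstream genes?

Builds a dose-response-like profile (9 contrasts with amplitudes 0..2),
then repeatedly removes a random 20% of the HYP's genes and correlates the
re-scored profile with the original (Spearman).  Values near 1 mean the
conclusions survive curation changes to the gene signature.
"""

import numpy as np

from npascore import SyntheticSpec, generate_contrast, generate_hyp, generate_universe, robustness_experiment

spec = SyntheticSpec(n_background=2000, n_downstream=100, noise_sd=0.5, seed=3)
universe, _ = generate_universe(spec)
hyp = generate_hyp(spec, universe)
contrasts = [
    generate_contrast(
        hyp, universe,
        SyntheticSpec(n_background=2000, n_downstream=100, amplitude=float(a),
                      noise_sd=0.5, seed=100 + i),
        name=f"amp={a:.2f}")
    for i, a in enumerate(np.linspace(0, 2, 9))
]

res = robustness_experiment(hyp, contrasts, method="gpi",
                            fraction_removed=0.2, n_rep=200, seed=0)
print(f"mean Spearman after 20% gene removal: {res['mean_spearman']:.3f}"
      f" +/- {res['sd_spearman']:.3f}  ({res['n_rep']} resamples)")
print("Near-1 correlation: the dose-response ranking is insensitive to")
print("removing a fifth of the signature's genes.")
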