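"""Is a score specific to the HYP's genes, or a data-set-wide trend?

Scores a truly perturbed HYP and, for comparison, a HYP of background genes,
against the same contrast.  Comparable HYPs are built by swapping each gene
for another with a similar number of known upstream controllers (same
"cadre"), so the null preserves how modulation-prone the gene set is.
"""

from npascore import (
    SyntheticSpec,
    build_cadres,
    generate_contrast,
    generate_hyp,
    generate_universe,
    specificity,
)

spec = SyntheticSpec(n_background=2000, n_downstream=100, amplitude=1.0,
                     noise_sd=0.5, seed=7)
universe, counts = generate_universe(spec)
hyp = generate_hyp(spec, universe)
contrast = generate_contrast(hyp, universe, spec)
cadres = build_cadres(counts, set(universe), cadre_size=100)

p_perturbed = specificity(hyp, contrast, "strength", cadres, n_null=1000, seed=0)

# a "decoy" HYP of genes the simulation never perturbed
decoy_spec = SyntheticSpec(n_background=2000, n_downstream=100, seed=999)
decoy = generate_hyp(decoy_spec, sorted(set(universe) - hyp.genes()))
p_decoy = specificity(decoy, contrast, "strength", cadres, n_null=1000, seed=0)

print(f"specificity p, perturbed HYP: {p_perturbed:.4f}  (p < 0.05: specific)")
print(f"specificity p, decoy HYP:     {p_decoy:.4f}  (unperturbed genes: not specific)")
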