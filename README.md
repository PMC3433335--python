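# npascore

Network Perturbation Amplitude (NPA) scoring: quantify how strongly a
treatment perturbs a biological process described by a causal network
model, using per-gene differential expression statistics.

## The problem

Gene-set and pathway tools typically answer *whether* a process is
enriched.  NPA scoring instead asks *how much* a process's activity
changed, and in *which direction*.  The unit of biology is a **HYP**: one
upstream entity (say, the transcriptional activity of NF-κB) together with
the downstream measurable genes it is known to regulate, each carrying a
regulation sign (+1 positive, −1 negative).  Larger signed causal network
models are flattened into a single *aggregated* HYP relative to a chosen
reference node, provided the model is causally consistent (no
negative-feedback cycle may force a node to carry both signs).

Given a contrast — one treated-versus-control comparison summarised per
gene by the log2 fold change β_i, its standard error sd_i, degrees of
freedom df_i, raw p-value, and linear-scale mean abundances — four
complementary amplitude scores are computed over the HYP's N genes:

| method   | formula | notes |
|----------|---------|-------|
| Strength | (1/N) Σ s_i·β_i | sign-adjusted mean log2 fold change |
| GPI      | (1/√N) Σ s_i·fndr_i·β_i | weights genes by fndr_i = 1 − fdr_i (BH) |
| MASS     | Σ s_i·(treated_i − control_i) / Σ (treated_i + control_i)/2 | linear abundance scale |
| EPI      | E[φ] under an evidence-weighted density on [−M, M] | up-weights strong responders; \|EPI\| ≤ M |

Two companion statistics qualify each score.  **Uncertainty** is a
confidence interval — analytic t-intervals for Strength and GPI (variance
by error propagation, effective degrees of freedom by Welch–Satterthwaite),
a parametric bias-corrected percentile bootstrap for MASS and EPI.
**Specificity** is a two-tailed permutation p-value comparing the observed
score with scores of "comparable HYPs" built by replacing every gene with a
different measured gene having a similar number of known upstream
controllers (genes ranked into cadres of 100).

A synthetic-data module generates gene universes with heavy-tailed
controller counts, random signed HYPs and consistent networks, and
contrasts with a known true amplitude, so every statistical property of the
pipeline can be verified without any external data.

## Worked example

```sh
python examples/score_a_hyp.py
```

simulates a 2000-gene universe, a 100-gene HYP perturbed with true
amplitude 1.0 and per-gene noise 0.5, and prints:

```
method         score    ci_low   ci_high
strength      1.0459    0.9478    1.1440
gpi           4.1952    1.7731    6.6173
mass          0.6546    0.5340    0.7624
epi           0.8199    0.7491    0.7845
```

Strength recovers the simulated amplitude (1.0 inside its interval); GPI
is on the √N-projection scale; MASS re-expresses the change on the linear
abundance scale; EPI's bias-corrected bootstrap interval is shifted below
the point score because parametric resampling biases EPI upward.  All four
intervals exclude 0: the process is confidently up-regulated.  Other
examples cover network aggregation (`aggregate_a_network.py`), the
specificity test (`specificity_test.py`) and robustness of score profiles
to gene removal (`robustness_to_gene_removal.py`).

A thin CLI wraps the same library:

```sh
npa simulate --out sim --seed 7
npa score --hyp sim/hyp.tsv --contrast sim/contrast.tsv --method gpi
npa specificity --hyp sim/hyp.tsv --contrast sim/contrast.tsv \
    --controllers sim/controller_counts.tsv --method strength
```

## Layout

- `src/npascore/hyp.py` — HYP/network data model, consistency, aggregation
- `src/npascore/contrasts.py` — contrast IO, BH-FDR, probe collapsing, alignment
- `src/npascore/scoring.py` — Strength, GPI, MASS, EPI
- `src/npascore/stats.py` — confidence intervals, cadres, specificity
- `src/npascore/synthetic.py` — simulation and fixture generators
- `src/npascore/cli.py` — `npa` command-line interface
- `docs/methods.md` — model assumptions, numerical choices, limitations
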