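"""Synthetic gene universes, HYPs, networks and contrasts with known truth.

The generator encodes the statistical model the scores assume: per-gene log2
differential expressions are independent estimators with standard error
``noise_sd`` and t-distributed errors (``df`` degrees of freedom, matching
the moderated-t framing, so the simulated p-values are exactly calibrated);
genes downstream of the perturbed HYP carry a mean signed effect
``amplitude`` on top of the noise, background genes are pure noise, so the
expected Strength equals the amplitude by linearity.  Controller counts for
cadre construction follow a geometric law -- a few promiscuously regulated
genes, a long tail of rarely regulated ones.

Also provides deterministic synthetic stand-in HYP files with the sizes and
ambiguity fractions characteristic of large literature-curated signatures,
and random causally-consistent signed networks for aggregation tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from npascore.contrasts import Contrast
from npascore.hyp import CausalNetwork, DownstreamEdge, Hyp, subsample_hyp
from npascore.scoring import EpiConfig, score
from npascore.contrasts import align_hyp_contrast


@dataclass
class SyntheticSpec:
    """Parameters of the simulated study.

    amplitude is the true mean signed log2 effect on HYP genes; noise_sd the
    per-gene standard error; df the error degrees of freedom; baseline_log2
    the mean log2 abundance around which treated/control are split so that
    log2(treated/control) = beta exactly.
    """

    n_background: int = 2000
    n_downstream: int = 100
    frac_negative: float = 0.25
    amplitude: float = 1.0
    noise_sd: float = 0.5
    df: float = 10.0
    baseline_log2: float = 7.0
    baseline_sd_log2: float = 1.5
    mean_controllers: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.frac_negative <= 1:
            raise ValueError("frac_negative must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_downstream > self.n_background:
            raise ValueError("n_downstream cannot exceed n_background")


def generate_universe(spec: SyntheticSpec) -> tuple[list[str], dict[str, int]]:
    """A gene universe with geometric-law upstream-controller counts."""
    if spec.n_background < 200:
        raise ValueError("universe too small to fill cadres (need n_background >= 200)")
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:06d}" for i in range(spec.n_background)]
    counts = rng.geometric(1.0 / spec.mean_controllers, size=spec.n_background)
    return genes, dict(zip(genes, (int(x) for x in counts)))


def generate_hyp(spec: SyntheticSpec, universe: list[str], upstream: str = "SYN") -> Hyp:
    """Random signed HYP over the universe with the configured sign mix."""
    if spec.n_downstream > len(universe):
        raise ValueError("requested HYP larger than the universe")
    rng = np.random.default_rng(spec.seed + 1)
    picks = rng.choice(len(universe), size=spec.n_downstream, replace=False)
    n_neg = round(spec.frac_negative * spec.n_downstream)
    signs = np.ones(spec.n_downstream, dtype=int)
    signs[rng.choice(spec.n_downstream, size=n_neg, replace=False)] = -1
    edges = [DownstreamEdge(universe[i], int(s)) for i, s in zip(picks, signs)]
    return Hyp(upstream=upstream, downstreams=edges)


def generate_contrast(
    h: Hyp, universe: list[str], spec: SyntheticSpec, name: str = "synthetic"
) -> Contrast:
    """Simulated contrast: beta = amplitude * sign + noise on HYP genes.

    Noise is sd * T(df); two-sided p-values come from the matching t test, so
    background p-values are exactly uniform.  Abundances split a log-normal
    per-gene baseline symmetrically, treated/control = 2^(b +/- beta/2).
    """
    rng = np.random.default_rng(spec.seed + 2)
    n = len(universe)
    sd = np.full(n, spec.noise_sd)
    beta = sd * rng.standard_t(spec.df, size=n)
    signs = h.signs()
    sign_vec = np.asarray([signs.get(g, 0) for g in universe], dtype=float)
    beta = beta + spec.amplitude * sign_vec
    p = 2.0 * sps.t.sf(np.abs(beta / sd), spec.df)
    baseline = rng.normal(spec.baseline_log2, spec.baseline_sd_log2, size=n)
    table = pd.DataFrame(
        {
            "beta": beta,
            "sd": sd,
            "df": np.full(n, spec.df),
            "p": p,
            "treated": np.exp2(baseline + beta / 2.0),
            "control": np.exp2(baseline - beta / 2.0),
        },
        index=pd.Index(universe, name="gene"),
    )
    return Contrast(name=name, table=table)


def robustness_experiment(
    h: Hyp,
    contrasts: list[Contrast],
    method: str = "gpi",
    fraction_removed: float = 0.2,
    n_rep: int = 1000,
    seed: int = 0,
    cfg: EpiConfig | None = None,
) -> dict:
    """Spearman stability of a score profile under random downstream removal.

    Scores the HYP against every contrast (the "profile"), then ``n_rep``
    times removes ``fraction_removed`` of the downstream genes at random and
    correlates the subsampled profile with the original.  Returns the mean
    and SD of the Spearman correlations.
    """
    if len(contrasts) < 3:
        raise ValueError("a score profile needs at least 3 contrasts")
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    matched = [align_hyp_contrast(h, c) for c in contrasts]
    original = np.asarray([score(m, method, cfg) for m in matched])
    rng = np.random.default_rng(seed)
    rhos = np.empty(n_rep)
    for r in range(n_rep):
        sub = subsample_hyp(h, fraction_removed, seed=int(rng.integers(2**31)))
        profile = np.asarray(
            [score(align_hyp_contrast(sub, c), method, cfg) for c in contrasts]
        )
        rhos[r] = 1.0 if np.array_equal(profile, original) else float(
            sps.spearmanr(original, profile).statistic
        )
    return {
        "method": method,
        "fraction_removed": fraction_removed,
        "n_rep": n_rep,
        "mean_spearman": float(np.mean(rhos)),
        "sd_spearman": float(np.std(rhos, ddof=1)) if n_rep > 1 else 0.0,
        "spearman": rhos,
    }


def random_consistent_network(
    n_nodes: int = 8,
    n_extra_edges: int = 4,
    hyp_size: int = 5,
    universe: list[str] | None = None,
    seed: int = 0,
) -> CausalNetwork:
    """A random causally consistent signed network with per-node HYPs.

    Builds a random spanning tree with random edge signs (always consistent),
    then adds extra edges whose signs are forced to close even-signed cycles.
    """
    rng = np.random.default_rng(seed)
    nodes = [f"N{i}" for i in range(n_nodes)]
    node_sign = {nodes[0]: 1}
    edges: list[tuple[str, str, int]] = []
    for i in range(1, n_nodes):
        parent = nodes[rng.integers(i)]
        sign = int(rng.choice([1, -1]))
        node_sign[nodes[i]] = node_sign[parent] * sign
        edges.append((parent, nodes[i], sign))
    for _ in range(n_extra_edges):
        i, j = rng.choice(n_nodes, size=2, replace=False)
        u, v = nodes[i], nodes[j]
        # edge sign consistent with the tree-implied node signs
        edges.append((u, v, node_sign[u] * node_sign[v]))
    if universe is None:
        universe = [f"G{i:06d}" for i in range(hyp_size * n_nodes * 2)]
    node_hyps = {}
    for node in nodes:
        picks = rng.choice(len(universe), size=hyp_size, replace=False)
        signs = rng.choice([1, -1], size=hyp_size)
        node_hyps[node] = Hyp(
            node, [DownstreamEdge(universe[k], int(s)) for k, s in zip(picks, signs)]
        )
    return CausalNetwork(nodes=set(nodes), edges=edges, node_hyps=node_hyps,
                         reference=nodes[0])


def corrupt_network(net: CausalNetwork) -> CausalNetwork:
    """Flip one non-tree edge sign to create an odd-signed (negative-feedback) cycle.

    Requires the network to contain at least one cycle; flipping any edge on
    a cycle makes the cycle's sign product odd.
    """
    import networkx as nx

    g = nx.Graph((s, t) for s, t, _ in net.edges)
    cycle = nx.cycle_basis(g)
    if not cycle:
        raise ValueError("network is a tree; no cycle to corrupt")
    u, v = cycle[0][0], cycle[0][1]
    edges = []
    flipped = False
    for s, t, sign in net.edges:
        if not flipped and {s, t} == {u, v}:
            edges.append((s, t, -sign))
            flipped = True
        else:
            edges.append((s, t, sign))
    return CausalNetwork(nodes=set(net.nodes), edges=edges,
                         node_hyps=dict(net.node_hyps), reference=net.reference)


# ---------------------------------------------------------------------------
# synthetic stand-ins for the four large literature-curated HYP tables
# ---------------------------------------------------------------------------

#: (label, unique downstream genes, distinct references, fraction ambiguous)
STANDIN_HYPS = [
    ("nfkb_direct", 155, 247, 0.04),
    ("ikk_nfkb_signaling", 992, 414, 0.06),
    ("tnf", 1741, 589, 0.07),
    ("e2f1_direct", 80, 54, 0.05),
]

#: genes shared between the tnf and e2f1_direct stand-ins
STANDIN_TNF_E2F1_OVERLAP = 32


def write_standin_hyp_suite(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write four synthetic stand-in HYP TSVs shaped like curated signatures.

    These are synthetic surrogates (not curated biology): each has the
    characteristic unique-gene count, reference count and ambiguous-gene
    fraction of a large literature-curated HYP, and the ``tnf`` /
    ``e2f1_direct`` pair shares exactly 32 downstream genes.  Ambiguous genes
    appear with both signs and duplicate (gene, sign) rows carry distinct
    evidence, so loading exercises merging and ambiguity filtering.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths: dict[str, Path] = {}
    tnf_genes: list[str] | None = None
    for label, n_genes, n_refs, frac_amb in STANDIN_HYPS:
        prefix = label[:3].upper()
        genes = [f"{prefix}{i:05d}" for i in range(n_genes)]
        if label == "tnf":
            tnf_genes = genes
        if label == "e2f1_direct":
            assert tnf_genes is not None
            shared = [tnf_genes[i] for i in
                      rng.choice(len(tnf_genes), STANDIN_TNF_E2F1_OVERLAP, replace=False)]
            genes = shared + genes[: n_genes - STANDIN_TNF_E2F1_OVERLAP]
        refs = [f"PMID:{int(x)}" for x in rng.integers(10_000_000, 30_000_000, n_refs)]
        rows = []
        upstream = label
        for g in genes:
            sign = "increases" if rng.random() > 0.3 else "decreases"
            rows.append((upstream, sign, g, refs[rng.integers(n_refs)]))
        # some genes get a second supporting row with the same sign but new evidence
        for g in rng.choice(genes, size=max(3, n_genes // 20), replace=False):
            sign = next(r[1] for r in rows if r[2] == g)
            rows.append((upstream, sign, g, refs[rng.integers(n_refs)]))
        # ambiguous genes: extra identifiers asserted with both signs
        n_amb = round(frac_amb * n_genes)
        for i in range(n_amb):
            g = f"{prefix}AMB{i:04d}"
            rows.append((upstream, "increases", g, refs[rng.integers(n_refs)]))
            rows.append((upstream, "decreases", g, refs[rng.integers(n_refs)]))
        df = pd.DataFrame(rows, columns=["upstream", "relation", "gene", "evidence"])
        path = out_dir / f"synthetic_{label}.hyp.tsv"
        df.to_csv(path, sep="\t", index=False)
        paths[label] = path
    return paths


def simulate_to_dir(spec: SyntheticSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write universe, controller counts, HYP and contrast TSVs plus a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    universe, counts = generate_universe(spec)
    h = generate_hyp(spec, universe)
    c = generate_contrast(h, universe, spec)
    paths = {
        "controller_counts": out_dir / "controller_counts.tsv",
        "hyp": out_dir / "hyp.tsv",
        "contrast": out_dir / "contrast.tsv",
        "manifest": out_dir / "manifest.json",
    }
    pd.DataFrame({"gene": universe, "n_controllers": [counts[g] for g in universe]}).to_csv(
        paths["controller_counts"], sep="\t", index=False
    )
    pd.DataFrame(
        [
            (h.upstream, "increases" if d.sign > 0 else "decreases", d.gene, "")
            for d in h.downstreams
        ],
        columns=["upstream", "relation", "gene", "evidence"],
    ).to_csv(paths["hyp"], sep="\t", index=False)
    c.table.rename_axis("gene").reset_index().to_csv(paths["contrast"], sep="\t", index=False)
    manifest = {"spec": asdict(spec), "files": {k: str(v) for k, v in paths.items()}}
    paths["manifest"].write_text(json.dumps(manifest, indent=2) + "\n")
    return paths
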