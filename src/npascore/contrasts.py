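"""Contrast tables and HYP/contrast alignment.

A contrast is one treated-versus-control comparison summarised per gene:
log2 differential expression beta, its standard error sd, the degrees of
freedom df of the t statistic, the raw p-value, and (for MASS) linear-scale
mean abundances under treatment and control.  False discovery rates are
Benjamini-Hochberg adjusted over all measured genes (the transcriptome-wide
multiplicity), and the false non-discovery rate fndr = 1 - fdr is the
per-gene belief weight used by GPI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from npascore.hyp import Hyp

logger = logging.getLogger(__name__)

_OPTIONAL_COLS = ("sd", "df", "p", "treated", "control")


class ContrastError(ValueError):
    """Malformed contrast table or misaligned HYP/contrast pair."""


@dataclass
class Contrast:
    """Per-gene differential results for one treated-vs-control comparison."""

    name: str
    table: pd.DataFrame  # indexed by gene

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ContrastError(f"duplicate gene rows in contrast {self.name!r}: {dups[:5]}")
        if "beta" not in self.table.columns:
            raise ContrastError(f"contrast {self.name!r} lacks mandatory column 'beta'")
        if "sd" in self.table.columns:
            sd = self.table["sd"].dropna()
            if (sd <= 0).any():
                raise ContrastError(f"non-positive sd values in contrast {self.name!r}")
        for col in ("treated", "control"):
            if col in self.table.columns and (self.table[col].dropna() < 0).any():
                raise ContrastError(f"negative {col} abundances in contrast {self.name!r}")

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def has(self, col: str) -> bool:
        return col in self.table.columns and self.table[col].notna().all()


@dataclass
class MatchedInput:
    """Parallel per-gene vectors over the HYP-and-contrast gene intersection.

    The per-gene alignment every score implicitly requires: signs ``s`` from
    the HYP, statistics from the contrast, in lexicographic gene order.
    Columns absent from the contrast are ``None`` and the operations needing
    them refuse at call time.
    """

    genes: np.ndarray  # dtype object/str
    s: np.ndarray  # +1/-1
    beta: np.ndarray
    sd: np.ndarray | None
    df: np.ndarray | None
    p: np.ndarray | None
    fdr: np.ndarray | None
    fndr: np.ndarray | None
    treated: np.ndarray | None
    control: np.ndarray | None
    n_missing: int = 0

    @property
    def n_used(self) -> int:
        return len(self.genes)

    def require(self, *cols: str) -> None:
        for col in cols:
            if getattr(self, col) is None:
                raise ContrastError(
                    f"operation needs contrast column {col!r}, absent from input"
                )


def read_contrast(path: str | Path, name: str | None = None) -> Contrast:
    """Read a contrast TSV (columns ``gene beta [sd df p treated control]``)."""
    path = Path(path)
    if not path.exists():
        raise ContrastError(f"contrast file not found: {path}")
    df = pd.read_csv(path, sep="\t")
    if "gene" not in df.columns or "beta" not in df.columns:
        raise ContrastError(f"contrast file {path} needs columns 'gene' and 'beta'")
    df["gene"] = df["gene"].astype(str)
    for col in ["beta", *(c for c in _OPTIONAL_COLS if c in df.columns)]:
        df[col] = pd.to_numeric(df[col], errors="raise")
    # MASS is defined on linear-scale abundances; derive them when only
    # per-condition log2 values are supplied
    for cond in ("treated", "control"):
        log_col = f"log2_{cond}"
        if cond not in df.columns and log_col in df.columns:
            df[cond] = 2.0 ** pd.to_numeric(df[log_col], errors="raise")
            df = df.drop(columns=log_col)
    df = df.set_index("gene")
    # drop all-NaN optional columns so `has` reflects real availability
    df = df.dropna(axis=1, how="all")
    return Contrast(name=name or path.stem, table=df)


def write_contrast(c: Contrast, path: str | Path) -> None:
    c.table.rename_axis("gene").reset_index().to_csv(path, sep="\t", index=False)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ContrastError("empty p-value vector")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ContrastError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _probe_class(probe: str) -> str | None:
    """Classify an expression-array probe-set id as 'at', 's_at' or None (excluded).

    Only plain "_at" and "_s_at" designs measure a transcript cleanly enough
    to keep; cross-hybridising and other qualified designs ("_x_at", "_a_at",
    ...) are excluded outright.
    """
    if not probe.endswith("_at"):
        return None
    base = probe[: -len("_at")]
    head, _, qual = base.rpartition("_")
    if head and len(qual) == 1 and qual.isalpha():
        return "s_at" if qual == "s" else None
    return "at"


def select_probesets(
    probe_map: dict[str, set[str]],
    probe_fdr: dict[str, np.ndarray],
) -> dict[str, str]:
    """Collapse probe sets to one representative probe per gene.

    Four-rule cascade, applied in order: (1) keep only "at"/"s_at" probe
    designs; (2) discard probes mapping to multiple genes; (3) per gene,
    prefer "at" over "s_at" probes; (4) among the remainder, pick the probe
    with the lowest geometric mean FDR-adjusted p across all contrasts (ties
    broken lexicographically by probe id).
    """
    if not probe_map:
        raise ContrastError("empty probe map")
    candidates: dict[str, list[tuple[str, str]]] = {}
    n_excluded = n_multi = 0
    for probe, genes in probe_map.items():
        cls = _probe_class(probe)
        if cls is None:
            n_excluded += 1
            continue
        if len(genes) != 1:
            n_multi += 1
            continue
        (gene,) = genes
        candidates.setdefault(gene, []).append((probe, cls))

    chosen: dict[str, str] = {}
    for gene, cands in candidates.items():
        ats = [p for p, cls in cands if cls == "at"]
        pool = ats if ats else [p for p, _ in cands]
        if len(pool) == 1:
            chosen[gene] = pool[0]
            continue

        def geo_mean(probe: str) -> float:
            fdr = np.asarray(probe_fdr[probe], dtype=float)
            return float(np.exp(np.mean(np.log(np.maximum(fdr, np.finfo(float).tiny)))))

        chosen[gene] = min(pool, key=lambda pr: (geo_mean(pr), pr))
    logger.info(
        "probe selection: %d genes resolved; %d probes excluded by design, %d multi-gene",
        len(chosen), n_excluded, n_multi,
    )
    return chosen


def align_hyp_contrast(h: Hyp, c: Contrast) -> MatchedInput:
    """Match a HYP against a contrast into parallel score-input vectors.

    Genes are the HYP/contrast intersection in lexicographic order; HYP genes
    missing from the contrast reduce N and are counted in ``n_missing``.  If
    the contrast lacks fdr, it is computed from the raw p-values over *all*
    measured genes (the array-wide multiplicity), then restricted to the HYP.
    """
    signs = h.signs()
    common = sorted(set(signs) & set(c.genes))
    n_missing = h.n - len(common)
    if not common:
        raise ContrastError(
            f"no overlap between HYP {h.upstream!r} genes and contrast {c.name!r}"
        )
    if n_missing:
        logger.warning(
            "HYP %s: %d of %d genes absent from contrast %s; N reduced to %d",
            h.upstream, n_missing, h.n, c.name, len(common),
        )

    tab = c.table
    fdr_all = None
    if c.has("fdr"):
        fdr_all = tab["fdr"].to_numpy(dtype=float)
    elif c.has("p"):
        fdr_all = bh_fdr(tab["p"].to_numpy(dtype=float))
    fdr_series = pd.Series(fdr_all, index=tab.index) if fdr_all is not None else None

    sub = tab.loc[common]

    def col(name: str) -> np.ndarray | None:
        if name in sub.columns and sub[name].notna().all():
            return sub[name].to_numpy(dtype=float)
        return None

    fdr = fdr_series.loc[common].to_numpy(dtype=float) if fdr_series is not None else None
    return MatchedInput(
        genes=np.asarray(common, dtype=object),
        s=np.asarray([signs[g] for g in common], dtype=int),
        beta=sub["beta"].to_numpy(dtype=float),
        sd=col("sd"),
        df=col("df"),
        p=col("p"),
        fdr=fdr,
        fndr=1.0 - fdr if fdr is not None else None,
        treated=col("treated"),
        control=col("control"),
        n_missing=n_missing,
    )
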