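"""Gene-level accessibility indices, divergence testing and SAGE binning.

The accessibility index of a gene is the mean library-size-normalized hit
count per retained half-site within the gene body, divided by the same
quantity from the in-vitro DAM-methylated naked-DNA control; an index of 1
means the tissue chromatin was as accessible as protein-free DNA.  Genes
qualify only if at least ``min_sites`` half-sites inside the gene were hit
at least once in at least one sample of the comparison, and genes with
zero control coverage are excluded (no pseudocounts).

Between-sample divergence of raw per-gene tag counts is assessed with an
exact conditional binomial test (doubled smaller tail) together with a
fold-change criterion on per-million-normalized counts; the boundary
utility traces the smallest imbalance satisfying both criteria, the curve
drawn over gene scatter plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .reads import HitTable
from .tagdb import TagDatabase

__all__ = [
    "gene_mean_hits",
    "gene_halfsite_counts",
    "accessibility_index",
    "divergence_test",
    "gene_divergence",
    "divergence_boundary",
    "sage_bin_averages",
]

PER_MILLION = 1_000_000.0


def _halfsite_index(db: TagDatabase) -> pd.DataFrame:
    """Retained half-sites with their GATC midpoints (site_pos + 2)."""
    t = db.retained_tags
    return pd.DataFrame(
        {
            "id": t["id"].to_numpy(),
            "contig": t["contig"].to_numpy(),
            "mid": (t["site_pos"] + 2).to_numpy(),
        }
    )


def _sites_in_gene(hs: pd.DataFrame, gene) -> pd.DataFrame:
    m = (
        (hs["contig"] == gene.contig)
        & (hs["mid"] >= gene.txStart)
        & (hs["mid"] < gene.txEnd)
    )
    return hs[m]


def gene_mean_hits(
    hits: HitTable, gene, db: TagDatabase
) -> tuple[int, float]:
    """(n_half_sites, mean hits-per-million per half-site) for one gene.

    ``gene`` needs attributes contig, txStart, txEnd.  Retained half-sites
    are assigned by GATC midpoint in [txStart, txEnd).  Mean is NaN for a
    gene spanning no retained half-sites or an empty library.
    """
    sel = _sites_in_gene(_halfsite_index(db), gene)
    n = len(sel)
    if n == 0 or hits.aligned == 0:
        return n, float("nan")
    scale = PER_MILLION / hits.aligned
    mean = np.mean([hits.count(int(i)) for i in sel["id"]]) * scale
    return n, float(mean)


def gene_halfsite_counts(
    tables: list[HitTable], genes: pd.DataFrame, db: TagDatabase
) -> pd.DataFrame:
    """Raw per-gene, per-sample summed counts and per-gene site bookkeeping.

    One row per gene: n_half_sites, per-sample total raw counts
    (``raw_<sample>``), per-sample mean hits-per-million per half-site
    (``mean_<sample>``) and ``n_hit_sites`` = number of half-sites hit at
    least once in at least one of the samples.
    """
    hs = _halfsite_index(db)
    arrays = {t.sample: t.count_array(db) for t in tables}
    aligned = {t.sample: max(t.aligned, 1) for t in tables}
    rows = []
    for gene in genes.itertuples():
        sel = _sites_in_gene(hs, gene)
        ids = sel["id"].to_numpy()
        rec: dict[str, object] = {
            "gene_id": gene.gene_id,
            "n_half_sites": len(ids),
        }
        any_hit = np.zeros(len(ids), dtype=bool)
        for label, arr in arrays.items():
            c = arr[ids] if len(ids) else np.zeros(0, dtype=np.int64)
            rec[f"raw_{label}"] = int(c.sum())
            rec[f"mean_{label}"] = (
                float(c.mean() * PER_MILLION / aligned[label])
                if len(ids)
                else float("nan")
            )
            any_hit |= c > 0
        rec["n_hit_sites"] = int(any_hit.sum())
        rows.append(rec)
    return pd.DataFrame(rows)


def accessibility_index(
    tissue: HitTable,
    control: HitTable,
    genes: pd.DataFrame,
    db: TagDatabase,
    min_sites: int = 4,
) -> pd.DataFrame:
    """Per-gene accessibility index: tissue mean / control mean.

    Genes are kept when >= min_sites half-sites within the gene were each
    hit at least once in at least one of the two samples, and the control
    mean is positive.  Means are hits-per-million per half-site, so the
    index is invariant to library size.
    """
    per_gene = gene_halfsite_counts([tissue, control], genes, db)
    tcol, ccol = f"mean_{tissue.sample}", f"mean_{control.sample}"
    keep = (per_gene["n_hit_sites"] >= min_sites) & (per_gene[ccol] > 0)
    out = per_gene[keep].copy()
    out["tissue_mean"] = out[tcol]      # robust to tissue == control
    out["control_mean"] = out[ccol]
    out["index"] = out["tissue_mean"] / out["control_mean"]
    return out[
        ["gene_id", "n_half_sites", "n_hit_sites",
         "tissue_mean", "control_mean", "index"]
    ].reset_index(drop=True)


def divergence_test(x: int, y: int, n1: int, n2: int) -> tuple[float, float]:
    """Exact conditional binomial divergence of two counts.

    Conditional on the total t = x + y, x ~ Binomial(t, n1/(n1+n2)) under
    the null of equal per-million representation; p is the doubled smaller
    tail, capped at 1.  The fold change is computed on per-million
    normalized counts (infinite when one count is zero).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    if x < 0 or y < 0 or x + y == 0:
        raise ValueError("need non-negative counts with x + y > 0")
    t = x + y
    pr = n1 / (n1 + n2)
    p = 2.0 * min(stats.binom.cdf(x, t, pr), stats.binom.sf(x - 1, t, pr))
    xn, yn = x / n1, y / n2
    if xn == 0.0 or yn == 0.0:
        fold = float("inf")
    else:
        fold = max(xn / yn, yn / xn)
    return fold, float(min(p, 1.0))


def gene_divergence(
    t1: HitTable, t2: HitTable, genes: pd.DataFrame, db: TagDatabase
) -> pd.DataFrame:
    """Fold and p-value per gene for a pair of samples (raw summed counts).

    Genes with x = y = 0 are undefined points and excluded.
    """
    per_gene = gene_halfsite_counts([t1, t2], genes, db)
    n1, n2 = max(t1.aligned, 1), max(t2.aligned, 1)
    x = per_gene[f"raw_{t1.sample}"].to_numpy()
    y = per_gene[f"raw_{t2.sample}"].to_numpy()
    keep = (x + y) > 0
    res = [divergence_test(int(a), int(b), n1, n2)
           for a, b in zip(x[keep], y[keep])]
    out = per_gene.loc[keep, ["gene_id"]].copy()
    out["x"], out["y"] = x[keep], y[keep]
    out["fold"] = [f for f, _ in res]
    out["p_value"] = [p for _, p in res]
    return out.reset_index(drop=True)


def divergence_boundary(
    n1: int,
    n2: int,
    fold: float = 2.0,
    alpha: float = 0.05,
    t_max: int = 500,
) -> pd.DataFrame:
    """Smallest imbalance at each total meeting both divergence criteria.

    For each total t = x + y up to t_max, finds the smallest x >= y-side
    imbalance with fold >= ``fold`` on per-million counts and p < alpha;
    returns both branches as (x, y) pairs for plotting.  At small t no
    point passes the significance criterion and the boundary is absent; at
    large t the fold criterion dominates and x/y approaches ``fold``
    (for n1 = n2).
    """
    rows = []
    for t in range(1, t_max + 1):
        lo = int(np.ceil(t / 2))
        for x in range(lo, t + 1):
            y = t - x
            f, p = divergence_test(x, y, n1, n2)
            if f >= fold and p < alpha:
                rows.append((t, x, y))
                break
    upper = pd.DataFrame(rows, columns=["total", "x", "y"])
    lower = upper.rename(columns={"x": "y", "y": "x"})[["total", "x", "y"]]
    upper["branch"], lower["branch"] = "upper", "lower"
    return pd.concat([upper, lower], ignore_index=True)


def sage_bin_averages(
    indices: pd.DataFrame,
    expression: pd.DataFrame,
    cap: int = 9,
) -> pd.DataFrame:
    """Mean accessibility index per exact SAGE score 0..cap-1, plus an
    aggregate ``"9+"`` bin for scores >= cap.

    ``indices`` needs columns gene_id and index; ``expression`` gene_id and
    sage_score.  Bins partition the genes with defined indices; empty bins
    are omitted.
    """
    merged = indices.merge(expression, on="gene_id")
    labels = [str(s) for s in range(cap)] + [f"{cap}+"]
    rows = []
    for lab in labels:
        if lab.endswith("+"):
            sel = merged["sage_score"] >= cap
        else:
            sel = merged["sage_score"] == int(lab)
        if sel.any():
            rows.append(
                (lab, float(merged.loc[sel, "index"].mean()), int(sel.sum()))
            )
    return pd.DataFrame(rows, columns=["bin", "mean_index", "n_genes"])
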