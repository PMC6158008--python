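"""Reciprocal differential expression and distance-resolved effect analysis.

The DE engine is a deliberately simple negative-binomial Wald test:
median-of-ratios size factors, per-gene method-of-moments dispersion with a
trend floor, and a Wald test of the log2 fold change of the recruitment
condition against the pooled controls, BH-corrected.  It trades the
refinements of a full DE package for transparency, and is validated by
calibration and planted-effect recovery rather than output identity.

Downstream, genes are classified by the joint activation/repression
outcome (a gene up under activation and down under repression is the
operational signature of enhancer dependence), annotated with the signed
distance from the TSS to the centre of the nearest targeted-family
instance, and analysed by distance decile and by 40-kb distance bins with
rank-sum tests against far genes.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, GeneModel, RepeatInstance

RECIPROCAL_LABELS = (
    "reciprocal", "a_only", "i_only", "both_same_direction",
    "both_other_pattern", "nonsig",
)

_LN2_SQ = math.log(2.0) ** 2
_PSEUDO = 0.5
_DISP_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# NB Wald differential expression

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over genes with all-positive counts."""
    pos = counts[(counts > 0).all(axis=1)]
    if pos.empty:
        raise ValueError("no gene has all-positive counts; cannot normalise")
    logs = np.log(pos.values.astype(float))
    ref = logs.mean(axis=1, keepdims=True)  # log geometric mean
    sf = np.exp(np.median(logs - ref, axis=0))
    return pd.Series(sf, index=counts.columns)


def _pooled_dispersion(norm: np.ndarray, groups: Sequence[np.ndarray]) -> np.ndarray:
    """Method-of-moments NB dispersion from within-group residual variance."""
    n_genes = norm.shape[0]
    ss = np.zeros(n_genes)
    df = 0
    for idx in groups:
        sub = norm[:, idx]
        if sub.shape[1] >= 2:
            ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
            df += sub.shape[1] - 1
    if df == 0:
        raise ValueError("need >= 2 samples in some group to estimate dispersion")
    var = ss / df
    mu = norm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (var - mu) / np.maximum(mu, 1e-12) ** 2
    return np.maximum(disp, _DISP_FLOOR)


def _trend_floor(disp: np.ndarray, mu: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Floor per-gene dispersions at the median of their expression stratum.

    Moment dispersion estimates from few replicates scatter widely and
    understate the variance for roughly half the genes; flooring at the
    stratum median keeps the Wald test conservative without costing power
    on strong effects.
    """
    order = np.argsort(mu, kind="stable")
    edges = np.array_split(order, n_bins)
    floor = np.full_like(disp, _DISP_FLOOR)
    for idx in edges:
        if len(idx):
            floor[idx] = np.median(disp[idx])
    return np.maximum(disp, floor)


def de_test(
    matrix: CountMatrix,
    recruitment: str = "recruitment",
    controls: tuple[str, ...] = ("control_a", "control_b"),
    min_mean: float = 1.0,
) -> pd.DataFrame:
    """NB Wald test of recruitment vs pooled controls for one effector.

    Returns a frame indexed by gene_id with base_mean, lfc, se, pvalue and
    padj (BH over tested genes); genes below min_mean normalised counts are
    excluded from testing (padj NaN).
    """
    rec_samples = matrix.samples_for(recruitment)
    ctrl_samples = [s for c in controls for s in matrix.samples_for(c)]
    if len(rec_samples) < 2 or len(ctrl_samples) < 2:
        raise ValueError("need >= 2 samples per pooled group")

    counts = matrix.counts
    sf = size_factors(counts)
    norm = counts.values / sf.values[None, :]
    cols = list(counts.columns)
    rec_idx = np.array([cols.index(s) for s in rec_samples])
    ctrl_idx = np.array([cols.index(s) for s in ctrl_samples])
    group_idx = [
        np.array([cols.index(s) for s in matrix.samples_for(cond)])
        for cond in sorted({matrix.conditions[s] for s in cols})
    ]

    mu_all = norm.mean(axis=1)
    tested = mu_all >= min_mean
    disp = _trend_floor(_pooled_dispersion(norm, group_idx), mu_all)

    mu1 = norm[:, rec_idx].mean(axis=1) + _PSEUDO
    mu0 = norm[:, ctrl_idx].mean(axis=1) + _PSEUDO
    lfc = np.log2(mu1 / mu0)
    v1 = mu1 + disp * mu1**2
    v0 = mu0 + disp * mu0**2
    se2 = (v1 / (len(rec_idx) * mu1**2) + v0 / (len(ctrl_idx) * mu0**2)) / _LN2_SQ
    se = np.sqrt(se2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / se, 0.0)
    pval = 2.0 * stats.norm.sf(np.abs(z))

    padj = np.full(len(counts), np.nan)
    if tested.any():
        padj[tested] = multipletests(pval[tested], method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "base_mean": mu_all,
            "lfc": lfc,
            "se": se,
            "pvalue": pval,
            "padj": padj,
            "tested": tested,
        },
        index=counts.index,
    )


def de_table(
    activation: pd.DataFrame, repression: pd.DataFrame
) -> pd.DataFrame:
    """Join the two effector contrasts into one per-gene DE table."""
    t = pd.DataFrame(index=activation.index)
    t["base_mean"] = activation["base_mean"]
    t["lfc_a"] = activation["lfc"]
    t["padj_a"] = activation["padj"]
    t["lfc_i"] = repression["lfc"]
    t["padj_i"] = repression["padj"]
    t["tested"] = activation["tested"] & repression["tested"]
    return t


# ---------------------------------------------------------------------------
# reciprocal classification

def classify_reciprocal(de: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Partition genes by the joint activation/repression outcome.

    reciprocal: up under activation AND down under repression, both
    significant -- the enhancer-dependence signature.
    """
    for col in ("lfc_a", "padj_a", "lfc_i", "padj_i"):
        if col not in de.columns:
            raise ValueError(f"DE table missing contrast column {col}")
    sig_a = (de["padj_a"] < alpha).fillna(False)
    sig_i = (de["padj_i"] < alpha).fillna(False)
    up_a, dn_a = de["lfc_a"] > 0, de["lfc_a"] < 0
    up_i, dn_i = de["lfc_i"] > 0, de["lfc_i"] < 0
    labels = pd.Series("nonsig", index=de.index, name="label")
    labels[sig_a & ~sig_i] = "a_only"
    labels[~sig_a & sig_i] = "i_only"
    both = sig_a & sig_i
    labels[both] = "both_same_direction"  # same signs and zero-lfc edge cases
    labels[both & up_a & dn_i] = "reciprocal"
    labels[both & dn_a & up_i] = "both_other_pattern"
    return labels


# ---------------------------------------------------------------------------
# distance annotation

def annotate_distance(
    genes: Sequence[GeneModel],
    instances: Sequence[RepeatInstance],
    target_family: str,
) -> pd.DataFrame:
    """Signed TSS distance to the nearest targeted-family instance centre.

    Sign follows the gene's orientation: negative = the instance lies
    upstream of the promoter.  Ties go to the smaller genomic coordinate.
    Genes on chromosomes without any instance get infinite distance and
    undefined side/orientation.
    """
    fam = [r for r in instances if r.family == target_family]
    if not fam:
        raise ValueError(f"no instances of family {target_family!r}")
    by_chrom: dict[str, list[RepeatInstance]] = {}
    for r in fam:
        by_chrom.setdefault(r.chrom, []).append(r)
    for rows in by_chrom.values():
        rows.sort(key=lambda r: r.center)
    centers = {c: np.array([r.center for r in rows]) for c, rows in by_chrom.items()}

    out = []
    for g in genes:
        if g.chrom not in centers:
            out.append(
                {"gene_id": g.gene_id, "nearest_instance": None,
                 "signed_distance": np.inf, "abs_distance": np.inf,
                 "side": None, "orientation": None, "downstream_mode": None}
            )
            continue
        cs = centers[g.chrom]
        rows = by_chrom[g.chrom]
        j = int(np.searchsorted(cs, g.tss))
        best = None
        for k in (j - 1, j):
            if 0 <= k < len(cs):
                d = abs(g.tss - int(cs[k]))
                if best is None or d < best[0] or (d == best[0] and cs[k] < cs[best[1]]):
                    best = (d, k)
        d, k = best
        inst = rows[k]
        signed = (inst.center - g.tss) * (1 if g.strand == "+" else -1)
        side = "upstream" if signed < 0 else "downstream"
        orientation = "same" if inst.strand == g.strand else "opposite"
        downstream_mode = None
        if side == "downstream":
            downstream_mode = "co-directional" if orientation == "same" else "convergent"
        out.append(
            {"gene_id": g.gene_id, "nearest_instance": inst.instance_id,
             "signed_distance": signed, "abs_distance": d,
             "side": side, "orientation": orientation,
             "downstream_mode": downstream_mode}
        )
    return pd.DataFrame(out).set_index("gene_id")


def decile_analysis(labels: pd.Series, distances: pd.DataFrame) -> pd.DataFrame:
    """Counts of each label per |distance| decile over all labelled genes.

    Deciles are computed over the absolute distance of every gene in
    `labels` (ties broken by gene id), giving 10 near-equal bins; the
    boundary columns report each decile's distance range.
    """
    genes = labels.index
    if len(genes) < 10:
        raise ValueError("need >= 10 genes for a decile analysis")
    d = distances.loc[genes, "abs_distance"]
    order = sorted(genes, key=lambda g: (d[g], g))
    decile = pd.Series(0, index=genes, dtype=int)
    n = len(order)
    for rank, g in enumerate(order):
        decile[g] = min(9, rank * 10 // n) + 1
    frame = pd.DataFrame({"label": labels, "decile": decile, "abs_distance": d})
    counts = (
        frame.pivot_table(index="decile", columns="label", aggfunc="size", fill_value=0)
        .reindex(range(1, 11), fill_value=0)
    )
    bounds = frame.groupby("decile")["abs_distance"].agg(["min", "max"])
    counts["dist_min"] = bounds["min"]
    counts["dist_max"] = bounds["max"]
    return counts


# ---------------------------------------------------------------------------
# rank-sum machinery (exact enumeration for small n, tie- and
# continuity-corrected normal approximation otherwise)

def rank_sum_test(x: Sequence[float], y: Sequence[float], switchover: int = 20) -> float:
    """Two-sided Wilcoxon-Mann-Whitney p-value.

    Exact enumeration of the rank-sum distribution (average ranks for
    ties) when n_x + n_y <= switchover; otherwise the normal approximation
    with tie correction and a 0.5 continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("empty sample in rank-sum test")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    if n1 + n2 <= switchover:
        return _rank_sum_exact(ranks, n1, r1)
    return _rank_sum_normal(ranks, n1, n2, r1)


def _rank_sum_exact(ranks: np.ndarray, n1: int, r1: float) -> float:
    n = len(ranks)
    mean = n1 * (n + 1) / 2.0
    obs = abs(r1 - mean)
    total = 0
    hits = 0
    for comb in itertools.combinations(range(n), n1):
        s = ranks[list(comb)].sum()
        total += 1
        if abs(s - mean) >= obs - 1e-9:
            hits += 1
    return hits / total


def _rank_sum_normal(ranks: np.ndarray, n1: int, n2: int, r1: float) -> float:
    n = n1 + n2
    mean = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / ((n) * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = (abs(r1 - mean) - 0.5) / math.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(max(z, 0.0))))


@dataclass
class BinTestResult:
    center: int  # signed bp
    n_genes: int
    median_lfc: float
    pvalue: float


def distance_bin_tests(
    de: pd.DataFrame,
    distances: pd.DataFrame,
    lfc_column: str = "lfc_a",
    bin_width: int = 40_000,
    max_dist: int = 400_000,
) -> list[BinTestResult]:
    """Rank-sum tests of per-bin log2 fold changes against pooled far genes.

    A gene joins the bin centred at round(signed distance / bin) * bin
    (half away from zero); genes beyond max_dist pool into two far bins
    that together form the reference set.
    """
    common = de.index.intersection(distances.index)
    d = distances.loc[common, "signed_distance"].to_numpy(float)
    lfc = de.loc[common, lfc_column].to_numpy(float)
    finite = np.isfinite(d) & np.isfinite(lfc)
    d, lfc = d[finite], lfc[finite]
    centers = np.sign(d) * np.floor(np.abs(d) / bin_width + 0.5) * bin_width
    far = np.abs(centers) > max_dist
    if not far.any():
        raise ValueError("empty far-gene reference set")
    ref = lfc[far]

    results: list[BinTestResult] = []
    for c in sorted(set(centers[~far].astype(int))):
        sel = (centers == c) & ~far
        vals = lfc[sel]
        p = rank_sum_test(vals, ref)
        results.append(BinTestResult(int(c), int(sel.sum()), float(np.median(vals)), p))
    # the two far bins are reported without a test (they are the reference)
    for sign, name in ((-1, "far_upstream"), (1, "far_downstream")):
        sel = far & (np.sign(centers) == sign)
        if sel.any():
            results.append(
                BinTestResult(int(sign * (max_dist + bin_width)), int(sel.sum()),
                              float(np.median(lfc[sel])), float("nan"))
            )
    return results


def orientation_summary(
    reciprocal_genes: Sequence[str], distances: pd.DataFrame
) -> pd.DataFrame:
    """2x2 counts of nearest-instance side x relative orientation."""
    sub = distances.loc[list(reciprocal_genes)]
    table = pd.DataFrame(
        0, index=["upstream", "downstream"], columns=["same", "opposite"]
    )
    for _, row in sub.iterrows():
        if row["side"] in table.index and row["orientation"] in table.columns:
            table.loc[row["side"], row["orientation"]] += 1
    return table


def overlap_enrichment(
    set_a: set[str], set_b: set[str], universe: set[str]
) -> tuple[float, float]:
    """Odds ratio and two-sided Fisher exact p for membership overlap."""
    if not universe:
        raise ValueError("empty universe")
    if not (set_a <= universe and set_b <= universe):
        raise ValueError("sets must be subsets of the universe")
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = len(universe) - a - b - c
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)
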