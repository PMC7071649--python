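"""Expression analysis: FPKM filtering, log transform, hierarchical
expression blocks, tissue-specificity z-score calls, hormone-response
calls, and qPCR relative quantification (2^-ddCt) with Welch's t-test.

Conventions: a gene is "expressed" when its FPKM reaches ``min_fpkm``
(default 1.0) in at least one sample; heat values are log2(FPKM + 1);
tissue specificity flags samples whose per-gene z-score exceeds 3
(strictly); hormone response requires |log2 fold change| >= 1 at some
timepoint on (FPKM + 1) ratios.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import t as t_dist

__all__ = [
    "BlockAssignment",
    "SpecificityCall",
    "HormoneResponse",
    "QpcrResult",
    "filter_expressed",
    "log_heat",
    "cluster_blocks",
    "tissue_specific",
    "hormone_response",
    "welch_test",
    "ddct",
]

logger = logging.getLogger(__name__)


@dataclass
class BlockAssignment:
    blocks: dict[str, int]  # gene -> block id (1..k)
    k: int
    linkage_method: str
    metric: str
    euclidean_fallback: list[str] = field(default_factory=list)


@dataclass
class SpecificityCall:
    z: pd.DataFrame  # genes x samples z-scores
    flagged: dict[str, list[str]]  # gene -> samples with z > threshold
    threshold: float


@dataclass
class HormoneResponse:
    calls: pd.DataFrame  # genes x hormones, values in {up, down, none}
    max_log2fc: pd.DataFrame  # signed log2FC at the strongest timepoint
    best_timepoint: pd.DataFrame
    multi_hormone_genes: list[str]  # responsive to >= 2 hormones

    @property
    def multi_hormone_count(self) -> int:
        return len(self.multi_hormone_genes)


@dataclass(frozen=True)
class QpcrResult:
    gene: str
    condition: str
    rq: float
    delta_ct: float
    delta_delta_ct: float
    welch_t: float | None
    df: float | None
    p_two_sided: float | None

    @property
    def stars(self) -> str:
        if self.p_two_sided is None:
            return ""
        if self.p_two_sided < 0.01:
            return "**"
        if self.p_two_sided < 0.05:
            return "*"
        return ""


def filter_expressed(
    matrix: pd.DataFrame, min_fpkm: float = 1.0
) -> tuple[pd.DataFrame, list[str]]:
    """Drop genes never reaching ``min_fpkm`` in any sample.

    Returns (retained matrix, excluded gene ids).  The boundary is
    inclusive: a gene peaking exactly at ``min_fpkm`` is retained.
    """
    if matrix.empty:
        raise ValueError("empty expression matrix")
    if (matrix.to_numpy() < 0).any():
        raise ValueError("FPKM values must be non-negative")
    keep = matrix.max(axis=1) >= min_fpkm
    excluded = list(matrix.index[~keep])
    return matrix.loc[keep], excluded


def log_heat(matrix: pd.DataFrame) -> pd.DataFrame:
    """log2(FPKM + 1) heat values (monotone, zero maps to zero)."""
    if (matrix.to_numpy() < 0).any():
        raise ValueError("negative values in expression matrix")
    return np.log2(matrix + 1.0)


def cluster_blocks(
    matrix: pd.DataFrame,
    k: int = 7,
    method: str = "average",
    metric: str = "correlation",
) -> BlockAssignment:
    """Agglomerative hierarchical clustering of gene expression profiles
    cut into ``k`` blocks.

    Default distance is 1 - Pearson correlation with average linkage.
    Constant rows (undefined correlation) are clustered separately by a
    Euclidean fallback: each is assigned to the block whose centroid is
    nearest; the fallback genes are recorded and logged.  Block ids are
    renumbered 1..k in order of first appearance down the gene list.
    """
    n = len(matrix)
    if k > n:
        raise ValueError(f"k={k} exceeds number of genes ({n})")
    vals = matrix.to_numpy(dtype=float)
    if metric == "correlation":
        variable = vals.std(axis=1) > 0
    else:
        variable = np.ones(n, dtype=bool)
    fallback = list(matrix.index[~variable])
    if fallback:
        logger.info("Euclidean fallback for %d constant rows", len(fallback))
    core = vals[variable]
    if len(core) < k:
        raise ValueError(
            f"k={k} exceeds number of non-constant genes ({len(core)})"
        )
    if len(core) > 1:
        dist = pdist(core, metric=metric)
        Z = linkage(dist, method=method)
        raw = fcluster(Z, t=k, criterion="maxclust")
    else:
        raw = np.array([1])
    blocks: dict[str, int] = {}
    genes_core = list(matrix.index[variable])
    for gene, b in zip(genes_core, raw):
        blocks[gene] = int(b)
    if fallback:
        centroids = {
            b: core[raw == b].mean(axis=0) for b in np.unique(raw)
        }
        for gene in fallback:
            row = matrix.loc[gene].to_numpy(dtype=float)
            nearest = min(
                sorted(centroids), key=lambda b: float(np.linalg.norm(row - centroids[b]))
            )
            blocks[gene] = int(nearest)
    # renumber in order of first appearance for determinism
    remap: dict[int, int] = {}
    for gene in matrix.index:
        b = blocks[gene]
        if b not in remap:
            remap[b] = len(remap) + 1
        blocks[gene] = remap[b]
    return BlockAssignment(
        blocks=blocks, k=k, linkage_method=method, metric=metric,
        euclidean_fallback=fallback,
    )


def tissue_specific(
    matrix: pd.DataFrame, z_threshold: float = 3.0
) -> SpecificityCall:
    """Per-gene z-scores across samples; flag samples with z strictly above
    the threshold.  Constant rows (sd = 0) yield all-zero z-scores and no
    flags."""
    if matrix.shape[1] < 2:
        raise ValueError("need at least two samples for z-scores")
    vals = matrix.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (vals - mean) / sd, 0.0)
    zdf = pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
    flagged = {
        gene: list(matrix.columns[z[i] > z_threshold])
        for i, gene in enumerate(matrix.index)
        if (z[i] > z_threshold).any()
    }
    return SpecificityCall(z=zdf, flagged=flagged, threshold=z_threshold)


def hormone_response(
    control: pd.Series,
    treated: dict[str, pd.DataFrame],
    fc_threshold: float = 1.0,
    min_fpkm: float = 1.0,
) -> HormoneResponse:
    """Call hormone responsiveness from control FPKM and per-hormone
    treated FPKM over timepoints.

    log2FC = log2((treated + 1) / (control + 1)) per timepoint; a gene
    responds to a hormone iff max |log2FC| >= fc_threshold and the winning
    condition (treated at the best timepoint, or control) reaches
    ``min_fpkm``.  Direction follows the sign of the strongest fold change.
    """
    genes = list(control.index)
    calls = pd.DataFrame("none", index=genes, columns=list(treated))
    maxfc = pd.DataFrame(0.0, index=genes, columns=list(treated))
    best_tp = pd.DataFrame("", index=genes, columns=list(treated))
    for hormone, tdf in treated.items():
        if list(tdf.index) != genes:
            raise ValueError(
                f"gene set for hormone {hormone!r} does not match control"
            )
        fc = np.log2((tdf.add(1.0)).div(control + 1.0, axis=0))
        idx = fc.abs().to_numpy().argmax(axis=1)
        cols = np.array(fc.columns)[idx]
        best = fc.to_numpy()[np.arange(len(genes)), idx]
        treated_best = tdf.to_numpy()[np.arange(len(genes)), idx]
        expressed = np.maximum(treated_best, control.to_numpy()) >= min_fpkm
        responsive = (np.abs(best) >= fc_threshold) & expressed
        maxfc[hormone] = best
        best_tp[hormone] = cols
        calls[hormone] = np.where(
            responsive, np.where(best > 0, "up", "down"), "none"
        )
    n_resp = (calls != "none").sum(axis=1)
    multi = list(calls.index[n_resp >= 2])
    return HormoneResponse(
        calls=calls, max_log2fc=maxfc, best_timepoint=best_tp,
        multi_hormone_genes=multi,
    )


def welch_test(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test, two-sided.

    Returns (t, df, p).  With both sample variances zero: p = 1 for equal
    means (t = 0), p = 0 otherwise (t = +-inf).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    diff = a.mean() - b.mean()
    if se2 == 0.0:
        if diff == 0.0:
            return 0.0, float(na + nb - 2), 1.0
        return math.copysign(math.inf, diff), float(na + nb - 2), 0.0
    t = diff / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * float(t_dist.sf(abs(t), df))
    return float(t), float(df), p


def ddct(
    ct_table: pd.DataFrame,
    control_condition: str,
) -> list[QpcrResult]:
    """Relative expression by the 2^-ddCt method, per gene and condition.

    ``ct_table`` columns: gene, condition, replicate, ct_target,
    ct_reference.  dCt is computed per replicate (target minus reference),
    ddCt = mean dCt(condition) - mean dCt(control), RQ = 2^-ddCt.  Welch's
    t-test compares per-replicate dCt values of the condition against the
    control; with a single replicate the test is skipped (with a warning).
    """
    required = {"gene", "condition", "replicate", "ct_target", "ct_reference"}
    if not required <= set(ct_table.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    df = ct_table.copy()
    df["dct"] = df["ct_target"] - df["ct_reference"]
    results: list[QpcrResult] = []
    for gene, sub in df.groupby("gene", sort=False):
        conds = sub.groupby("condition", sort=False)["dct"].apply(list).to_dict()
        if control_condition not in conds:
            raise ValueError(
                f"gene {gene!r}: control condition {control_condition!r} missing"
            )
        ctrl = conds[control_condition]
        ctrl_mean = float(np.mean(ctrl))
        for cond, dcts in conds.items():
            dct_mean = float(np.mean(dcts))
            dd = dct_mean - ctrl_mean
            rq = 2.0**-dd
            if cond == control_condition:
                t, dfree, p = 0.0, float(2 * len(ctrl) - 2), 1.0
            elif len(dcts) < 2 or len(ctrl) < 2:
                logger.warning(
                    "gene %s condition %s: single replicate, test skipped",
                    gene, cond,
                )
                t = dfree = p = None
            else:
                t, dfree, p = welch_test(dcts, ctrl)
            results.append(
                QpcrResult(
                    gene=gene, condition=cond, rq=rq, delta_ct=dct_mean,
                    delta_delta_ct=dd, welch_t=t, df=dfree, p_two_sided=p,
                )
            )
    return results
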