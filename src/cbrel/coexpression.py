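"""Gene filtering and construction of target-correlated gene sets.

Two filters precede the correlation sweep, applied in order: (1) genes
whose mean RPKM over all samples falls strictly below the dataset's
25th-percentile threshold are dropped (low-expression filter); (2) genes
with more than ``max_missing_z`` missing z-scores across the included
specimens are dropped.  Each remaining gene's z profile is then
correlated (Pearson, pairwise-complete) with the target gene's profile,
and genes beyond the +/-0.6 thresholds form the positively and
negatively correlated sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionDataset
from .relative import RelativeZMatrix

logger = logging.getLogger(__name__)

UPPER_R_THRESHOLD = 0.6
LOWER_R_THRESHOLD = -0.6
MAX_MISSING_Z = 5


@dataclass(frozen=True)
class GeneFilterReport:
    n_input: int
    n_low_expression_dropped: int
    quartile_threshold: float
    n_missingness_dropped: int
    n_retained: int

    def __post_init__(self) -> None:
        total = self.n_low_expression_dropped + self.n_missingness_dropped + self.n_retained
        if total != self.n_input:
            raise ValueError("filter report counts do not partition the input")


@dataclass(frozen=True)
class GeneSetPair:
    positive: frozenset[str]
    negative: frozenset[str]
    upper: float = UPPER_R_THRESHOLD
    lower: float = LOWER_R_THRESHOLD

    def __post_init__(self) -> None:
        if self.positive & self.negative:
            raise ValueError("positive and negative sets overlap")


def filter_genes(
    ds: ExpressionDataset,
    zm: RelativeZMatrix,
    max_missing_z: int = MAX_MISSING_Z,
    quartile: float = 25.0,
    apply_quartile_filter: bool = True,
) -> tuple[list[str], GeneFilterReport]:
    """Apply the low-expression and z-missingness filters, in that order.

    ``ds`` should already have never-expressed genes removed, so the
    quartile threshold is computed over genes with some expression.  The
    threshold is the ``quartile``-th percentile (linear interpolation) of
    per-gene mean RPKM over all samples, missing values excluded; genes
    strictly below it are dropped.  Genes with more than ``max_missing_z``
    missing z values among the matrix's specimens are then dropped.
    """
    genes = ds.values.index
    means = ds.values.mean(axis=1)
    if apply_quartile_filter:
        threshold = float(np.percentile(means.dropna().to_numpy(), quartile))
        low = means < threshold
    else:
        threshold = float("nan")
        low = pd.Series(False, index=genes)
    after_quartile = genes[~low]

    missing = zm.z.loc[after_quartile].isna().sum(axis=1)
    too_missing = missing > max_missing_z
    retained = after_quartile[~too_missing.to_numpy()]

    report = GeneFilterReport(
        n_input=len(genes),
        n_low_expression_dropped=int(low.sum()),
        quartile_threshold=threshold,
        n_missingness_dropped=int(too_missing.sum()),
        n_retained=len(retained),
    )
    logger.info(
        "filter_genes: %d -> %d (quartile threshold %.6g dropped %d; "
        "missingness > %d dropped %d)",
        report.n_input, report.n_retained, threshold,
        report.n_low_expression_dropped, max_missing_z, report.n_missingness_dropped,
    )
    return list(retained), report


def _pairwise_pearson(X: np.ndarray, t: np.ndarray, min_pairs: int):
    """Row-wise Pearson of X against t over pairwise-complete columns.

    Returns (r, n_pairs); r is NaN where fewer than ``min_pairs``
    complete pairs exist or either side is constant.
    """
    valid = ~np.isnan(X) & ~np.isnan(t)[None, :]
    n = valid.sum(axis=1).astype(float)
    Xv = np.where(valid, X, 0.0)
    Tv = np.where(valid, t[None, :], 0.0)
    sx = Xv.sum(axis=1)
    st = Tv.sum(axis=1)
    sxx = (Xv * Xv).sum(axis=1)
    stt = (Tv * Tv).sum(axis=1)
    sxt = (Xv * Tv).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxt - sx * st / n
        vx = sxx - sx * sx / n
        vt = stt - st * st / n
        r = cov / np.sqrt(vx * vt)
    r = np.clip(r, -1.0, 1.0)
    r[(n < min_pairs) | ~(np.sqrt(np.maximum(vx, 0) * np.maximum(vt, 0)) > 0)] = np.nan
    return r, n.astype(int)


def correlate_all(
    zm: RelativeZMatrix,
    target_gene: str,
    retained_genes: list[str],
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Pearson correlation of every retained gene's z profile with the target's.

    Correlations are pairwise-complete over specimens where both profiles
    are present.  Returns a DataFrame indexed by gene with columns
    ``n_pairs``, ``r``, ``p`` (two-sided t-test, n_pairs - 2 df); genes
    with fewer than ``min_pairs`` pairs have missing r and p.  The target
    gene itself is not a row.
    """
    if target_gene not in zm.z.index:
        raise KeyError(f"target gene {target_gene!r} not in z-matrix")
    genes = [g for g in retained_genes if g != target_gene]
    X = zm.z.loc[genes].to_numpy(float)
    t = zm.z.loc[target_gene].to_numpy(float)
    r, n = _pairwise_pearson(X, t, min_pairs)
    with np.errstate(invalid="ignore", divide="ignore"):
        df = n - 2
        tstat = r * np.sqrt(df / (1.0 - r * r))
        p = 2.0 * stats.t.sf(np.abs(tstat), np.maximum(df, 1))
        p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    p[np.isnan(r)] = np.nan
    return pd.DataFrame({"n_pairs": n, "r": r, "p": p}, index=pd.Index(genes, name="gene"))


def build_sets(
    ct: pd.DataFrame,
    upper: float = UPPER_R_THRESHOLD,
    lower: float = LOWER_R_THRESHOLD,
) -> GeneSetPair:
    """Threshold the correlation table into positive/negative gene sets.

    Membership is strict (r > upper, r < lower); genes with missing r
    join neither set.
    """
    r = ct["r"]
    positive = frozenset(ct.index[r > upper])
    negative = frozenset(ct.index[r < lower])
    return GeneSetPair(positive, negative, upper, lower)


def write_gene_sets(sets: GeneSetPair, pos_path, neg_path, gmt_path=None) -> None:
    for path, genes in ((pos_path, sets.positive), (neg_path, sets.negative)):
        with open(path, "w") as fh:
            for g in sorted(genes):
                fh.write(g + "\n")
    if gmt_path is not None:
        with open(gmt_path, "w") as fh:
            fh.write(
                "positively_correlated\tr > {:g}\t{}\n".format(
                    sets.upper, "\t".join(sorted(sets.positive))
                )
            )
            fh.write(
                "negatively_correlated\tr < {:g}\t{}\n".format(
                    sets.lower, "\t".join(sorted(sets.negative))
                )
            )
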