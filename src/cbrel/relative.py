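"""Region-relative cerebellar z-scores and genome-wide centile benchmarks.

For each gene and specimen, cerebellar expression is expressed as a
z-score against that specimen's other grey-matter regions:

    z = (cerebellar - mean(other regions)) / sd(other regions)

with the sample standard deviation (divisor k - 1).  Cells where the
cerebellar value is missing, fewer than two other regions were sampled,
or the other-region SD is zero are missing, never 0 or +/-inf.  A gene's
z-score for one specimen can then be benchmarked against the z-scores of
every other gene in that specimen (the centile report).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .ages import AgePoint
from .io import ExpressionDataset

logger = logging.getLogger(__name__)


@dataclass
class RelativeZMatrix:
    """Genes x specimens matrix of cerebellar-relative z-scores.

    ``z`` has gene rows and donor-id columns (NaN = not computable);
    ``n_other_regions`` gives the per-cell count of non-cerebellar values
    behind the denominator, and ``ages`` maps each donor to its age.
    """

    z: pd.DataFrame
    n_other_regions: pd.DataFrame
    ages: dict[str, AgePoint]
    n_degenerate: int = 0

    @property
    def genes(self) -> list[str]:
        return list(self.z.index)

    @property
    def donor_ids(self) -> list[str]:
        return list(self.z.columns)

    def age_days(self) -> pd.Series:
        return pd.Series(
            {d: a.days_post_conception for d, a in self.ages.items()},
            name="age_days",
        ).loc[self.donor_ids]

    def subset_genes(self, genes) -> "RelativeZMatrix":
        genes = list(genes)
        return replace(
            self, z=self.z.loc[genes], n_other_regions=self.n_other_regions.loc[genes]
        )


def relative_z(ds: ExpressionDataset, log_transform: bool = False) -> RelativeZMatrix:
    """Compute the cerebellar-vs-rest z-score for every gene and specimen.

    Parameters
    ----------
    ds
        An expression dataset, normally after :func:`cbrel.io.select_specimens`.
    log_transform
        If True, z-score log2(RPKM + 1) instead of raw RPKM (robustness
        mode; the default analysis z-scores RPKM directly).
    """
    zcols: dict[str, np.ndarray] = {}
    ncols: dict[str, np.ndarray] = {}
    n_degenerate = 0
    for sp in ds.specimens:
        cb = ds.cerebellar_values(sp.donor_id)
        others = ds.non_cerebellar_values(sp.donor_id)
        if log_transform:
            cb = None if cb is None else np.log2(cb + 1.0)
            others = np.log2(others + 1.0)
        k = others.notna().sum(axis=1).to_numpy()
        mean = others.mean(axis=1).to_numpy()
        sd = others.std(axis=1, ddof=1).to_numpy()
        cbv = np.full(len(ds.genes), np.nan) if cb is None else cb.to_numpy(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (cbv - mean) / sd
        bad = (k < 2) | ~(sd > 0) | np.isnan(cbv)
        n_degenerate += int(((k >= 2) & ~(sd > 0) & ~np.isnan(cbv)).sum())
        z[bad] = np.nan
        zcols[sp.donor_id] = z
        ncols[sp.donor_id] = np.where(bad, 0, k)
    idx = pd.Index(ds.genes, name="gene")
    zm = RelativeZMatrix(
        z=pd.DataFrame(zcols, index=idx),
        n_other_regions=pd.DataFrame(ncols, index=idx, dtype=int),
        ages={sp.donor_id: sp.age for sp in ds.specimens},
        n_degenerate=n_degenerate,
    )
    if n_degenerate:
        logger.info("relative_z: %d degenerate (zero-SD) cells set missing", n_degenerate)
    return zm


def drop_never_expressed(ds: ExpressionDataset) -> tuple[ExpressionDataset, list[str]]:
    """Drop genes with no recorded expression in any region of any specimen.

    A gene is dropped iff every value is 0 or missing; a single positive
    RPKM anywhere keeps it.
    """
    arr = ds.values.to_numpy()
    with np.errstate(invalid="ignore"):
        expressed = np.nansum(arr > 0, axis=1) > 0
    kept = ds.values.index[expressed]
    dropped = ds.values.index[~expressed].tolist()
    logger.info("drop_never_expressed: dropped %d of %d genes", len(dropped), len(ds.genes))
    return ds.subset_genes(kept), dropped


def midrank_centile(background: np.ndarray, value: float) -> float:
    """Percentile rank of ``value`` in ``background`` with ties counted half.

    centile = 100 * (#below + 0.5 * #ties) / len(background)
    """
    background = np.asarray(background, dtype=float)
    if background.size == 0:
        raise ValueError("empty background")
    below = float(np.sum(background < value))
    ties = float(np.sum(background == value))
    return 100.0 * (below + 0.5 * ties) / background.size


def centile_benchmark(
    zm: RelativeZMatrix, target_gene: str, exclude_target: bool = True
) -> pd.DataFrame:
    """Benchmark one gene's z-score against all other genes, per specimen.

    Returns one row per specimen: the target's z, its midrank centile in
    the background z distribution, the background size, and the
    background's 5th/25th/50th/75th/95th centiles (linear interpolation).
    Specimens where the target z is missing get NaN statistics.
    """
    if target_gene not in zm.z.index:
        raise KeyError(f"target gene {target_gene!r} not in z-matrix")
    rows = []
    bg_matrix = zm.z.drop(index=target_gene) if exclude_target else zm.z
    for donor in zm.donor_ids:
        t = zm.z.at[target_gene, donor]
        bg = bg_matrix[donor].dropna().to_numpy()
        row = {
            "donor_id": donor,
            "age_days": zm.ages[donor].days_post_conception,
            "age_label": zm.ages[donor].raw_label,
            "target_z": t,
            "n_background": bg.size,
        }
        if np.isnan(t) or bg.size == 0:
            row.update(
                {q: np.nan for q in ("centile", "p5", "q25", "median", "q75", "p95")}
            )
        else:
            p5, q25, med, q75, p95 = np.percentile(bg, [5, 25, 50, 75, 95])
            row.update(
                centile=midrank_centile(bg, t),
                p5=p5, q25=q25, median=med, q75=q75, p95=p95,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def write_zmatrix(zm: RelativeZMatrix, z_path, specimens_path) -> None:
    """Serialise the z-matrix (gene x donor TSV, missing = empty field)
    plus a specimen sidecar with ages, for the CLI stage boundary."""
    zm.z.to_csv(z_path, sep="\t", na_rep="")
    pd.DataFrame(
        {
            "donor_id": zm.donor_ids,
            "age_label": [zm.ages[d].raw_label for d in zm.donor_ids],
        }
    ).to_csv(specimens_path, sep="\t", index=False)


def read_zmatrix(z_path, specimens_path) -> RelativeZMatrix:
    from .ages import parse_age

    z = pd.read_csv(z_path, sep="\t", index_col="gene")
    z.columns = z.columns.astype(str)
    meta = pd.read_csv(specimens_path, sep="\t", dtype=str)
    ages = {r.donor_id: parse_age(r.age_label) for r in meta.itertuples()}
    n = z.notna().astype(int) * 0  # counts not persisted across the boundary
    return RelativeZMatrix(z=z, n_other_regions=n, ages=ages)
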