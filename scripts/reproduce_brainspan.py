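#!/usr/bin/env python
"""Reproduce the real-data analysis given a local BrainSpan download.

Point this script at the three files of the "RNA-Seq Gencode v10
summarised to genes" distribution (expression_matrix.csv,
rows_metadata.csv, columns_metadata.csv; available from
www.brainspan.org/static/download.html — no download is performed here)
and it recomputes the full analysis for the ATM gene:

* specimen inclusion (cerebellar sample + >= 4 other regions) out of all donors;
* never-expressed gene exclusion and the retained-gene count;
* phase-1 / phase-2 Pearson r and p of the cerebellar-relative z-score
  against age, under both conventions for first-year infants (counted in
  both phases, or in phase 1 only);
* the number of specimens between 24 post-conception weeks and 1 year
  whose ATM z-score exceeds the genome-wide 95th centile;
* the lowest-quartile mean-RPKM threshold and the gene counts after the
  quartile and z-missingness filters;
* the sizes of the r > 0.6 and r < -0.6 correlated gene sets (and, with
  --gmt, their term overrepresentation).

Usage:
    python scripts/reproduce_brainspan.py \
        --matrix expression_matrix.csv --rows-meta rows_metadata.csv \
        --columns-meta columns_metadata.csv [--gmt go_bp.gmt] [--out report.json]
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

from cbrel.ages import BIRTH_DAYS, DAYS_PER_YEAR
from cbrel.coexpression import build_sets, correlate_all, filter_genes
from cbrel.enrichment import enrich, read_gmt
from cbrel.io import read_brainspan, select_specimens
from cbrel.relative import centile_benchmark, drop_never_expressed, relative_z
from cbrel.trajectory import default_phases, fit_phase


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--matrix", required=True, type=Path)
    ap.add_argument("--rows-meta", required=True, type=Path)
    ap.add_argument("--columns-meta", required=True, type=Path)
    ap.add_argument("--gmt", type=Path, default=None)
    ap.add_argument("--target-gene", default="ATM")
    ap.add_argument("--out", type=Path, default=None)
    args = ap.parse_args()

    report: dict = {}
    ds = read_brainspan(args.matrix, args.rows_meta, args.columns_meta)
    report["n_donors_total"] = len(ds.specimens)
    report["n_genes_total"] = len(ds.genes)

    included, excluded = select_specimens(ds)
    report["n_specimens_included"] = len(included.specimens)
    report["excluded"] = [[e.donor_id, e.reason] for e in excluded]

    included, dropped = drop_never_expressed(included)
    report["n_never_expressed_dropped"] = len(dropped)
    report["n_genes_retained"] = len(included.genes)

    zm = relative_z(included)
    for label, infants_in_phase2 in (
        ("infants_in_both_phases", True),
        ("infants_in_phase1_only", False),
    ):
        fits = {}
        for phase in default_phases(infants_in_phase2):
            f = fit_phase(zm, args.target_gene, phase)
            fits[phase.name] = {"n": f.n, "r": round(f.pearson_r, 4),
                                "p": float(f"{f.p_value:.3g}")}
        report[label] = fits

    centiles = centile_benchmark(zm, args.target_gene)
    window = centiles[
        (centiles.age_days >= 24 * 7.0)
        & (centiles.age_days <= BIRTH_DAYS + DAYS_PER_YEAR)
    ]
    report["target_above_p95_24pcw_to_1yr"] = [
        int((window.centile > 95).sum()),
        len(window),
    ]
    report["n_specimens_above_p75"] = int((centiles.centile > 75).sum())

    retained, filt = filter_genes(included, zm)
    report["lowest_quartile_rpkm_threshold"] = float(filt.quartile_threshold)
    report["n_after_quartile_filter"] = filt.n_input - filt.n_low_expression_dropped
    report["n_in_enrichment_universe"] = filt.n_retained

    ct = correlate_all(zm, args.target_gene, retained)
    sets = build_sets(ct)
    report["n_positively_correlated"] = len(sets.positive)
    report["n_negatively_correlated"] = len(sets.negative)

    if args.gmt is not None:
        ann = read_gmt(args.gmt)
        universe = frozenset(g for g in retained if g != args.target_gene)
        for label, genes in (("positive", sets.positive), ("negative", sets.negative)):
            table = enrich(genes, ann, universe)
            report[f"enrichment_{label}_top10"] = table.head(10).to_dict("records")

    print(json.dumps(report, indent=2))
    if args.out is not None:
        args.out.parent.mkdir(parents=True, exist_ok=True)
        with open(args.out, "w") as fh:
            json.dump(report, fh, indent=2)


if __name__ == "__main__":
    main()
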