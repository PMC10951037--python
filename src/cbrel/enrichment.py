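"""Overrepresentation analysis of gene sets against annotation terms.

Each annotation term is tested with a two-sided Fisher exact test on the
2x2 table (query vs rest) x (in term vs not), against a stated gene
universe.  Fold enrichment is the observed-over-expected ratio
(k/n)/(K/N); terms with fold > 1 are over-represented, fold < 1
under-represented — both directions fall out of the same two-sided
sweep.  Raw p-values are adjusted across all tested terms with the
Benjamini-Hochberg step-up procedure.

Annotations come from standard GMT files (term, description, member
genes, tab-separated).  No ontology-hierarchy propagation is performed:
the GMT's memberships are the contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


class GMTParseError(ValueError):
    pass


@dataclass
class AnnotationCollection:
    """Term id -> (name, member set), plus the gene universe."""

    terms: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]

    def harmonized(self, universe: frozenset[str]) -> "AnnotationCollection":
        """Restrict every term to ``universe``."""
        terms = {
            tid: (name, members & universe) for tid, (name, members) in self.terms.items()
        }
        return AnnotationCollection(terms, universe)


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> AnnotationCollection:
    """Parse a GMT file.  Duplicate members within a line are collapsed;
    the universe defaults to the union of all members unless given."""
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    union: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(
                    f"{path}:{lineno}: expected term, description and >= 1 member, "
                    f"got {len(fields)} field(s)"
                )
            tid, desc = fields[0], fields[1]
            members = frozenset(g for g in fields[2:] if g)
            if not members:
                raise GMTParseError(f"{path}:{lineno}: term {tid!r} has no members")
            if tid in terms:
                raise GMTParseError(f"{path}:{lineno}: duplicate term id {tid!r}")
            terms[tid] = (desc, members)
            union |= members
    uni = frozenset(universe) if universe is not None else frozenset(union)
    return AnnotationCollection(terms, uni)


def write_gmt(ann: AnnotationCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for tid, (desc, members) in ann.terms.items():
            fh.write("\t".join([tid, desc, *sorted(members)]) + "\n")


#: relative tie tolerance when comparing hypergeometric probabilities,
#: the same convention scipy and R use for the two-sided Fisher test
_TIE_EPS = 1e-7


def fisher_all_k(K: int, n: int, N: int) -> tuple[int, np.ndarray]:
    """Two-sided Fisher p for every attainable overlap k at fixed margins.

    Returns (k_min, p) where p[i] is the p-value for k = k_min + i: the
    total probability of outcomes no more likely than the observed one,
    over the hypergeometric support.
    """
    lo, hi = max(0, n - (N - K)), min(n, K)
    pmf = stats.hypergeom.pmf(np.arange(lo, hi + 1), N, K, n)
    ps = np.array([pmf[pmf <= pk * (1.0 + _TIE_EPS)].sum() for pk in pmf])
    return lo, np.minimum(ps, 1.0)


def fisher_two_sided(k: int, K: int, n: int, N: int) -> float:
    """Two-sided Fisher exact p for observing k query genes in a term.

    Equivalent to Fisher's exact test on the 2x2 table
    [[k, n - k], [K - k, N - K - n + k]] for a query of size n and a term
    of size K in a universe of size N.
    """
    if not 0 <= k <= min(n, K) or k < n - (N - K):
        raise ValueError(f"impossible overlap k={k} for K={K}, n={n}, N={N}")
    lo, ps = fisher_all_k(K, n, N)
    return float(ps[k - lo])


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, input order preserved.

    All inputs must lie in (0, 1]; adjusted values are capped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any(~(p > 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query: Iterable[str],
    ann: AnnotationCollection,
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Test every term for over/under-representation of ``query``.

    Query genes outside the universe are dropped (with a logged count).
    Returns one row per term — term_id, term_name, k, n, K, N, fold,
    p_raw, fdr, direction — sorted by fdr then term_id.  Terms with no
    members inside the universe are not tested.
    """
    uni = frozenset(universe) if universe is not None else ann.universe
    if not uni:
        raise ValueError("empty universe")
    q = frozenset(query)
    outside = q - uni
    if outside:
        logger.warning("enrich: %d query gene(s) outside the universe dropped", len(outside))
    q &= uni
    if not q:
        raise ValueError("empty query after universe harmonization")
    harm = ann.harmonized(uni)
    N, n = len(uni), len(q)
    rows = []
    for tid, (name, members) in harm.terms.items():
        K = len(members)
        if K == 0:
            continue
        k = len(q & members)
        expected = K * n / N
        fold = (k / n) / (K / N)
        rows.append(
            {
                "term_id": tid,
                "term_name": name,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "fold": fold,
                "p_raw": fisher_two_sided(k, K, n, N),
                "direction": "over" if fold > 1 else "under",
            }
        )
    if not rows:
        raise ValueError("no testable terms (all empty after harmonization)")
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p_raw"])
    out = out.sort_values(["fdr", "term_id"], ignore_index=True)
    return out[
        ["term_id", "term_name", "k", "n", "K", "N", "fold", "p_raw", "fdr", "direction"]
    ]
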