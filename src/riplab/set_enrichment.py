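"""Gene-set overlap and over-representation statistics.

Called target lists are compared with published gene sets by simple overlap
(count, percentage of the reference set, and an upper-tail hypergeometric
p-value given a gene universe), and annotation terms are tested for
over-representation with fold enrichment = (term frequency in targets) /
(term frequency in universe) and Benjamini-Hochberg correction across
terms.  Overlap percentages do not depend on the universe; p-values do.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError

__all__ = [
    "GeneSet",
    "OraResult",
    "OverlapResult",
    "ora_fold_enrichment",
    "overlap",
]


def _norm(ids: Iterable[str]) -> frozenset[str]:
    return frozenset(str(g).strip().lower() for g in ids)


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene ids; ids are case-normalized on construction."""

    name: str
    members: frozenset[str]

    @classmethod
    def from_ids(cls, name: str, ids: Iterable[str]) -> "GeneSet":
        return cls(name=name, members=_norm(ids))

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class OverlapResult:
    n_a: int
    n_b: int
    n_overlap: int
    pct_of_b: float
    p_value: float


@dataclass(frozen=True)
class OraResult:
    term: str
    n_term_in_targets: int
    n_term_in_universe: int
    fold_enrichment: float
    p_value: float
    q_value: float


def overlap(a: GeneSet, b: GeneSet, universe: GeneSet) -> OverlapResult:
    """Overlap of a with b, and the upper-tail hypergeometric p given a universe.

    p = P(X >= n_overlap) for X ~ Hypergeom(|universe|, |a|, |b|): the chance
    of drawing at least the observed overlap when |b| genes are sampled
    without replacement from the universe, |a| of which are "marked".
    """
    if len(b) == 0:
        raise InputError("reference set b is empty; percentage undefined")
    a_u = a.members & universe.members
    b_u = b.members & universe.members
    k = len(a.members & b.members)
    p = float(stats.hypergeom.sf(k - 1, len(universe), len(a_u), len(b_u)))
    return OverlapResult(
        n_a=len(a),
        n_b=len(b),
        n_overlap=k,
        pct_of_b=100.0 * k / len(b),
        p_value=p,
    )


def ora_fold_enrichment(
    targets: GeneSet,
    annotation: Mapping[str, Iterable[str]],
    universe: GeneSet,
) -> list[OraResult]:
    """Over-representation of annotation terms in a target list.

    Annotation gene sets are intersected with the universe before testing;
    one result per term with at least one target member, with fold
    enrichment, upper-tail hypergeometric p, and BH q-values computed across
    the tested terms.  Results are sorted by ascending p.
    """
    if len(universe) == 0:
        raise InputError("universe is empty")
    if not targets.members <= universe.members:
        raise InputError("targets must be a subset of the universe")
    n_universe = len(universe)
    n_targets = len(targets)
    rows: list[tuple[str, int, int, float, float]] = []
    for term, genes in annotation.items():
        term_set = _norm(genes) & universe.members
        k = len(term_set & targets.members)
        if k == 0:
            continue
        fold = (k / n_targets) / (len(term_set) / n_universe)
        p = float(stats.hypergeom.sf(k - 1, n_universe, len(term_set), n_targets))
        rows.append((term, k, len(term_set), fold, p))
    if not rows:
        return []
    _, qvals, _, _ = multipletests([r[4] for r in rows], method="fdr_bh")
    results = [
        OraResult(term, k, n_term, fold, p, float(q))
        for (term, k, n_term, fold, p), q in zip(rows, qvals)
    ]
    results.sort(key=lambda r: (r.p_value, r.term))
    return results
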