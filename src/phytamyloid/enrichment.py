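"""Per-term over-representation testing and heat-map matrix export.

Flagged (potentially amyloidogenic) proteins are tested for
over-representation against every annotation term using the one-sided
hypergeometric tail, with the whole valid proteome as the universe. A term
is *reported* when p < alpha (default 0.01) and at least ``min_interest``
(default 5) proteins of interest carry it; no multiple-testing correction is
applied inside this step — the raw alpha cut is the selection rule. For
cross-species heat maps, the cell value is the interest fraction
(flagged proteins with term / all proteins with term), zeroed wherever the
term is not reported in that species.

Annotations are taken as given: there is no ontology-graph propagation or
term decorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    n_universe: int
    n_term: int          # universe proteins annotated with the term
    n_interest: int
    n_overlap: int       # interest proteins annotated with the term
    p: float
    reported: bool
    p_source: str = "fisher"

    @property
    def interest_fraction(self) -> float:
        return self.n_overlap / self.n_term if self.n_term else 0.0


def term_enrichment(
    universe: set[str],
    interest: set[str],
    annotations: Mapping[str, set[str]],
    min_interest: int = 5,
    alpha: float = 0.01,
) -> list[EnrichmentResult]:
    """One-sided over-representation test for every term in the universe.

    ``annotations`` maps protein id -> set of term ids; ids outside the
    universe are ignored. p = P(overlap >= observed) under the
    hypergeometric null on (n_universe, n_term, n_interest).
    """
    if not interest <= universe:
        raise ValueError("interest set must be a subset of the universe")
    n_universe = len(universe)
    n_interest = len(interest)
    term_members: dict[str, set[str]] = {}
    for pid in universe:
        for term in annotations.get(pid, ()):
            term_members.setdefault(term, set()).add(pid)
    results = []
    for term in sorted(term_members):
        members = term_members[term]
        n_term = len(members)
        n_overlap = len(members & interest)
        # P(X >= n_overlap), X ~ Hypergeom(N=n_universe, K=n_term, n=n_interest)
        p = float(hypergeom.sf(n_overlap - 1, n_universe, n_term, n_interest))
        results.append(
            EnrichmentResult(
                term=term,
                n_universe=n_universe,
                n_term=n_term,
                n_interest=n_interest,
                n_overlap=n_overlap,
                p=p,
                reported=(p < alpha) and (n_overlap >= min_interest),
            )
        )
    return results


def enrichment_matrix(
    per_species_results: Mapping[str, Sequence[EnrichmentResult]],
    top_k: int = 30,
) -> pd.DataFrame:
    """Species x term matrix of interest fractions for heat-map export.

    Columns are the union over species of each species' ``top_k`` reported
    terms ranked by p (ties broken by term id for determinism); a cell is
    the interest fraction where the term is reported in that species and 0
    otherwise.
    """
    selected: list[str] = []
    for species in sorted(per_species_results):
        reported = [r for r in per_species_results[species] if r.reported]
        reported.sort(key=lambda r: (r.p, r.term))
        for r in reported[:top_k]:
            if r.term not in selected:
                selected.append(r.term)
    species_names = sorted(per_species_results)
    if not selected:
        return pd.DataFrame(index=species_names)
    matrix = pd.DataFrame(0.0, index=species_names, columns=selected)
    for species, results in per_species_results.items():
        for r in results:
            if r.reported and r.term in matrix.columns:
                matrix.at[species, r.term] = r.interest_fraction
    return matrix
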