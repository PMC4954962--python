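"""Hypergeometric term enrichment against an explicit gene universe.

Raw p-values are upper-tail hypergeometric probabilities computed with
log-space summation; multiple-hypothesis correction is Bonferroni by
default, with a resampling mode (corrected p = fraction of random same-size
gene lists whose best raw p beats the observed one) available.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class AnnotationSet:
    """Gene -> term mapping restricted to a background universe."""

    gene_to_terms: dict[str, set[str]]
    universe: set[str]
    term_to_genes: dict[str, set[str]] = field(init=False)

    def __post_init__(self) -> None:
        self.universe = set(self.universe)
        self.term_to_genes = {}
        for gene, terms in self.gene_to_terms.items():
            if gene not in self.universe:
                continue  # annotations outside the background are ignored
            for term in terms:
                self.term_to_genes.setdefault(term, set()).add(gene)
        # terms with zero universe members are excluded by construction

    @classmethod
    def from_tsv(cls, path: str | Path, universe: set[str]) -> "AnnotationSet":
        """Flat two-column (gene, term) TSV, optional header."""
        frame = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        if frame.shape[1] < 2:
            raise ValueError("annotation TSV needs two columns: gene, term")
        first = frame.iloc[0]
        if str(first[0]).lower() in ("gene", "gene_id"):
            frame = frame.iloc[1:]
        mapping: dict[str, set[str]] = {}
        for gene, term in zip(frame[0], frame[1]):
            mapping.setdefault(str(gene), set()).add(str(term))
        return cls(gene_to_terms=mapping, universe=set(universe))

    @classmethod
    def from_gaf(cls, path: str | Path, universe: set[str]) -> "AnnotationSet":
        """GAF 2.x subset reader: columns 2 (object id) and 5 (term id)."""
        mapping: dict[str, set[str]] = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("!") or not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 5:
                    continue
                mapping.setdefault(parts[1], set()).add(parts[4])
        return cls(gene_to_terms=mapping, universe=set(universe))

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"gene": gene, "term": term}
            for gene, terms in sorted(self.gene_to_terms.items())
            for term in sorted(terms)
        ]
        pd.DataFrame(rows, columns=["gene", "term"]).to_csv(path, sep="\t", index=False)


def _lchoose(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail probability P(X >= k) of a hypergeometric draw.

    Drawing ``n`` genes without replacement from a universe of ``N`` of
    which ``K`` carry the term: sums C(K,i) C(N-K,n-i) / C(N,n) for
    i = k..min(n,K), accumulated in log space.
    """
    for name, value in (("k", k), ("n", n), ("K", K), ("N", N)):
        if value != int(value) or value < 0:
            raise ValueError(f"{name} must be a non-negative integer")
    if not (k <= n <= N and K <= N):
        raise ValueError("require 0 <= k <= n <= N and K <= N")
    hi = min(n, K)
    if k == 0:
        return 1.0
    if k > hi:
        return 0.0
    lo = max(k, n - (N - K))  # below lo, C(N-K, n-i) vanishes
    if lo > hi:
        return 0.0
    log_denom = _lchoose(N, n)
    log_terms = [
        _lchoose(K, i) + _lchoose(N - K, n - i) - log_denom for i in range(lo, hi + 1)
    ]
    peak = max(log_terms)
    total = peak + math.log(sum(math.exp(t - peak) for t in log_terms))
    return float(min(math.exp(total), 1.0))


def correct_pvalues(
    p_raws,
    method: str = "bonferroni",
    n_resamples: int = 1000,
    seed: int | None = None,
    annotation: AnnotationSet | None = None,
    n_hits: int | None = None,
    m: int | None = None,
) -> np.ndarray:
    """Multiple-hypothesis correction over a family of raw p-values.

    ``bonferroni``: min(1, m * p) with m = number of tested terms
    (defaults to the length of ``p_raws``).
    ``resampling``: for each observed p, the fraction of ``n_resamples``
    random hit lists of size ``n_hits`` drawn from the annotation universe
    whose minimum raw p over all terms is <= the observed p (requires
    ``annotation`` and ``n_hits``).
    """
    p_raws = np.asarray(p_raws, dtype=float)
    if np.any((p_raws <= 0) | (p_raws > 1)):
        raise ValueError("raw p-values must lie in (0, 1]")
    m = p_raws.size if m is None else int(m)
    if method == "bonferroni":
        return np.minimum(1.0, m * p_raws)
    if method == "resampling":
        if annotation is None or n_hits is None:
            raise ValueError("resampling correction needs annotation and n_hits")
        if n_resamples < 100:
            warnings.warn("fewer than 100 resamples gives a coarse correction")
        rng = np.random.default_rng(seed)
        universe = sorted(annotation.universe)
        terms = sorted(annotation.term_to_genes)
        N = len(universe)
        best = np.empty(n_resamples)
        for i in range(n_resamples):
            draw = set(rng.choice(universe, size=n_hits, replace=False))
            best[i] = min(
                hypergeom_tail(
                    len(draw & annotation.term_to_genes[t]),
                    n_hits,
                    len(annotation.term_to_genes[t]),
                    N,
                )
                for t in terms
            )
        return np.array([(best <= p).mean() for p in p_raws])
    raise ValueError(f"unknown correction method {method!r}")


def enrich(
    hits: set[str],
    annotation: AnnotationSet,
    min_term_hits: int = 2,
    correction: str = "bonferroni",
    alpha: float = 0.05,
    n_resamples: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Score every annotated term against a hit list.

    Returns the full table (one row per term with at least one universe
    member and at least one hit) sorted by corrected then raw p, with a
    ``significant`` flag requiring p_corrected <= alpha AND
    k >= min_term_hits.  Hits outside the universe are dropped with a
    warning; an empty hit list is an error.
    """
    if not hits:
        raise ValueError("empty hit list")
    hits = set(hits)
    outside = hits - annotation.universe
    if outside:
        log.warning("dropping %d hits outside the universe", len(outside))
    scored = hits & annotation.universe
    if not scored:
        raise ValueError("no hits inside the universe")
    n = len(scored)
    N = len(annotation.universe)
    rows = []
    for term, members in annotation.term_to_genes.items():
        K = len(members)
        k = len(scored & members)
        if k < 1:
            continue
        relative = 100.0 * k / n
        background = 100.0 * K / N
        rows.append(
            {
                "term": term,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "relative_freq": relative,
                "background_freq": background,
                "fold": relative / background,
                "p_raw": hypergeom_tail(k, n, K, N),
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "term", "k", "n", "K", "N",
            "relative_freq", "background_freq", "fold", "p_raw",
        ],
    )
    if len(frame):
        frame["p_corrected"] = correct_pvalues(
            frame["p_raw"].to_numpy(),
            method=correction,
            n_resamples=n_resamples,
            seed=seed,
            annotation=annotation,
            n_hits=n,
            m=len(annotation.term_to_genes),
        )
        frame["significant"] = (frame["p_corrected"] <= alpha) & (
            frame["k"] >= min_term_hits
        )
        frame = frame.sort_values(
            ["p_corrected", "p_raw", "term"], kind="stable"
        ).reset_index(drop=True)
    else:
        frame["p_corrected"] = pd.Series(dtype=float)
        frame["significant"] = pd.Series(dtype=bool)
    return frame
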