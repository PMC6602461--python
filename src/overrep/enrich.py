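"""Over-representation analysis: cumulative hypergeometric testing of gene
lists against a term store.

Supports three query flavours:

* **unordered** — the classical ORA contract: for each term, the probability
  of observing at least ``k`` of its ``K`` members in a random draw of the
  ``n`` query genes from the ``N``-gene background.
* **ordered** — for a ranked list, every prefix (length 1..n) is tested and
  each term is reported at the prefix minimizing its p-value, together with
  that prefix length. Broader terms typically optimize at longer prefixes.
* **multi-list** — several named lists in one input (FASTA-like ``>name``
  headers), each analysed independently against the same background, plus a
  joint table over the union of terms significant in at least one list.

Only adjusted p-values are surfaced in the primary outputs; the adjustment
is Bonferroni, Benjamini–Hochberg, or the empirical min-p correction from
:mod:`overrep.correction` (tag ``gscs``, the default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import correction as corr
from ._tails import tail_array
from .annotation import GeneUniverse, TermStore, bitset_from_positions
from .idmap import Resolution

__all__ = [
    "Query",
    "EnrichmentRecord",
    "hypergeom_tail",
    "run_unordered",
    "run_ordered",
    "run_multiquery",
    "parse_query_text",
    "query_from_identifiers",
    "MultiQueryResult",
]


@dataclass(frozen=True)
class Query:
    """A resolved gene list as positions in a store's universe."""

    name: str
    genes: tuple[int, ...]
    ordered: bool = False
    provenance: tuple[Resolution, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("query genes must be unique")

    @property
    def size(self) -> int:
        return len(self.genes)

    @property
    def bitset(self) -> int:
        return bitset_from_positions(self.genes)


@dataclass(frozen=True)
class EnrichmentRecord:
    """One term x query result.

    ``N`` background size, ``K`` term size within the background, ``n``
    effective query size (the optimal prefix length for ordered queries),
    ``k`` intersection size. ``p_adj`` is the value to report; ``p_raw`` is
    kept for diagnostics and ranking ties.
    """

    query_name: str
    term_id: str
    source: str
    term_name: str
    N: int
    K: int
    n: int
    k: int
    p_raw: float
    p_adj: float
    method: str
    significant: bool
    prefix_length: int | None = None
    intersection_genes: tuple[str, ...] = ()
    evidence: tuple[str, ...] = ()


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail cumulative hypergeometric probability P(X >= k).

    X counts annotated genes in a size-``n`` draw without replacement from
    ``N`` genes of which ``K`` are annotated. Evaluated via the survival
    function in log-stable form; the result is floored at the smallest
    positive double so ``-log10`` transforms stay finite.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid bounds: N={N}, K={K}, n={n}")
    if not 0 <= k <= min(n, K):
        raise ValueError(f"k={k} outside [0, min(n={n}, K={K})]")
    if k == 0:
        return 1.0
    return float(tail_array(N, K, n, k))


def _adjust(
    p_raw: np.ndarray,
    method: str,
    store: TermStore,
    query_size: int,
    ordered: bool,
    null: corr.NullDistribution | None,
    R: int,
    seed: int | None,
) -> tuple[np.ndarray, corr.NullDistribution | None]:
    m = len(store.terms)
    if method == "bonferroni":
        return corr.bonferroni(p_raw, m), null
    if method == "fdr":
        return corr.bh_fdr(p_raw), null
    if method == "gscs":
        if null is None:
            null = corr.build_null(store, query_size, ordered=ordered, R=R, seed=seed)
        return corr.empirical_minp_adjust(p_raw, null, query_size, ordered), null
    raise ValueError(f"unknown correction tag {method!r}")


def run_unordered(
    query: Query,
    store: TermStore,
    method: str = "gscs",
    alpha: float = 0.05,
    null: corr.NullDistribution | None = None,
    R: int = 1000,
    seed: int | None = None,
) -> list[EnrichmentRecord]:
    """Test an unordered query against every term in the store.

    Intersection sizes come from bitset AND; the correction is applied over
    the family of all tested terms; records are flagged significant iff
    ``p_adj <= alpha``.
    """
    if query.size == 0:
        raise ValueError("empty query after projection onto the background")
    N = len(store.universe)
    n = query.size
    qbits = query.bitset
    K = np.array([t.size for t in store.terms])
    k = np.array([(t.members & qbits).bit_count() for t in store.terms])
    p_raw = tail_array(N, K, n, k)
    p_adj, _ = _adjust(p_raw, method, store, n, False, null, R, seed)
    records = []
    for j, term in enumerate(store.terms):
        inter = term.members & qbits
        genes = tuple(store.universe.genes[p] for p in _iter_bits(inter))
        records.append(
            EnrichmentRecord(
                query_name=query.name,
                term_id=term.term_id,
                source=term.source,
                term_name=term.name,
                N=N,
                K=int(K[j]),
                n=n,
                k=int(k[j]),
                p_raw=float(p_raw[j]),
                p_adj=float(min(1.0, p_adj[j])),
                method=method,
                significant=bool(p_adj[j] <= alpha),
                intersection_genes=genes,
                evidence=_evidence(term, genes),
            )
        )
    return records


def run_ordered(
    query: Query,
    store: TermStore,
    method: str = "gscs",
    alpha: float = 0.05,
    null: corr.NullDistribution | None = None,
    R: int = 1000,
    seed: int | None = None,
    stride: int = 1,
) -> list[EnrichmentRecord]:
    """Test every prefix of a ranked query; report each term at its best prefix.

    For each term the raw p-value is the minimum over prefix lengths
    ``l = 1..n`` (step ``stride``) of the tail at ``(N, K, l, k_l)``, with
    ties broken toward the smallest ``l``. Under Bonferroni/BH the family
    size is the number of terms (the per-term minimum is the test
    statistic); the ``gscs`` null simulates ordered queries and therefore
    absorbs the prefix multiplicity.
    """
    if not query.ordered:
        raise ValueError("run_ordered requires an ordered query")
    if query.size == 0:
        raise ValueError("empty query after projection onto the background")
    N = len(store.universe)
    n = query.size
    K = np.array([t.size for t in store.terms])
    member = np.zeros((n, len(store.terms)), dtype=bool)
    for i, pos in enumerate(query.genes):
        for j, term in enumerate(store.terms):
            if term.members >> pos & 1:
                member[i, j] = True
    k_cum = np.cumsum(member, axis=0)  # (n, T)
    lengths = np.arange(1, n + 1)
    keep = (lengths - 1) % stride == 0
    keep[-1] = True  # always include the full list
    p_mat = tail_array(N, K[None, :], lengths[keep, None], k_cum[keep])
    # smallest prefix on ties, where "tie" tolerates float noise in the tail
    p_min = p_mat.min(axis=0)
    best = np.argmax(p_mat <= p_min * (1 + 1e-9), axis=0)
    p_raw = p_mat[best, np.arange(p_mat.shape[1])]
    best_len = lengths[keep][best]
    p_adj, _ = _adjust(p_raw, method, store, n, True, null, R, seed)
    records = []
    for j, term in enumerate(store.terms):
        ell = int(best_len[j])
        prefix_bits = bitset_from_positions(query.genes[:ell])
        inter = term.members & prefix_bits
        genes = tuple(store.universe.genes[p] for p in _iter_bits(inter))
        records.append(
            EnrichmentRecord(
                query_name=query.name,
                term_id=term.term_id,
                source=term.source,
                term_name=term.name,
                N=N,
                K=int(K[j]),
                n=ell,
                k=int(k_cum[ell - 1, j]),
                p_raw=float(p_raw[j]),
                p_adj=float(min(1.0, p_adj[j])),
                method=method,
                significant=bool(p_adj[j] <= alpha),
                prefix_length=ell,
                intersection_genes=genes,
                evidence=_evidence(term, genes),
            )
        )
    return records


def _iter_bits(bits: int):
    pos = 0
    while bits:
        tz = (bits & -bits).bit_length() - 1
        pos += tz
        yield pos
        bits >>= tz + 1
        pos += 1


def _evidence(term, genes: tuple[str, ...]) -> tuple[str, ...]:
    if not term.evidence:
        return ()
    return tuple(term.evidence.get(g, "") for g in genes)


def parse_query_text(text: str) -> list[tuple[str, list[str]]]:
    """Split raw query text into named token lists.

    Tokens are whitespace-separated; ``#`` starts a comment; a ``>name``
    header opens a new list (FASTA style). Tokens before the first header
    form an implicit list named ``query_1``.
    """
    lists: list[tuple[str, list[str]]] = []
    current: list[str] | None = None
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith(">"):
            name = line[1:].strip() or f"query_{len(lists) + 1}"
            if lists and not lists[-1][1]:
                raise ValueError(f"empty gene list under header {lists[-1][0]!r}")
            current = []
            lists.append((name, current))
            continue
        if current is None:
            current = []
            lists.append(("query_1", current))
        current.extend(line.split())
    if not lists:
        raise ValueError("no query tokens found")
    if not lists[-1][1]:
        raise ValueError(f"empty gene list under header {lists[-1][0]!r}")
    return lists


def query_from_identifiers(
    name: str,
    identifiers,
    universe: GeneUniverse,
    ordered: bool = False,
    provenance: tuple[Resolution, ...] = (),
) -> tuple[Query, tuple[str, ...]]:
    """Project identifiers onto the universe, dropping (and reporting) those outside it.

    Duplicates collapse to the first occurrence; for ordered queries the
    input order is preserved exactly.
    """
    positions: list[int] = []
    seen: set[int] = set()
    dropped: list[str] = []
    for ident in identifiers:
        pos = universe.index.get(ident)
        if pos is None:
            dropped.append(ident)
        elif pos not in seen:
            seen.add(pos)
            positions.append(pos)
    return Query(name, tuple(positions), ordered, provenance), tuple(dropped)


@dataclass(frozen=True)
class MultiQueryResult:
    """Per-query records plus the joint comparison table."""

    records: dict[str, list[EnrichmentRecord]]
    joint: pd.DataFrame
    dropped: dict[str, tuple[str, ...]]


def run_multiquery(
    text: str,
    store: TermStore,
    method: str = "gscs",
    alpha: float = 0.05,
    ordered: bool = False,
    R: int = 1000,
    seed: int | None = None,
) -> MultiQueryResult:
    """Analyse every named list in a multi-query input independently.

    All lists share the store, background and correction settings; the
    joint table contains exactly the union of terms significant in at least
    one query, with one adjusted-p column per query. Null distributions for
    the empirical correction are cached per query size.
    """
    parsed = parse_query_text(text)
    records: dict[str, list[EnrichmentRecord]] = {}
    dropped: dict[str, tuple[str, ...]] = {}
    nulls: dict[int, corr.NullDistribution] = {}
    for name, tokens in parsed:
        query, missing = query_from_identifiers(name, tokens, store.universe, ordered)
        dropped[name] = missing
        null = None
        if method == "gscs":
            if query.size not in nulls:
                nulls[query.size] = corr.build_null(
                    store, query.size, ordered=ordered, R=R, seed=seed
                )
            null = nulls[query.size]
        runner = run_ordered if ordered else run_unordered
        records[name] = runner(
            query, store, method=method, alpha=alpha, null=null, R=R, seed=seed
        )
    keep_ids = {
        r.term_id for recs in records.values() for r in recs if r.significant
    }
    rows = []
    for term in store.terms:
        if term.term_id not in keep_ids:
            continue
        row: dict = {
            "source": term.source,
            "term_id": term.term_id,
            "term_name": term.name,
            "term_size": term.size,
        }
        for name, recs in records.items():
            rec = next(r for r in recs if r.term_id == term.term_id)
            row[f"p_adj_{name}"] = rec.p_adj
            row[f"significant_{name}"] = rec.significant
        rows.append(row)
    joint = pd.DataFrame(rows)
    return MultiQueryResult(records, joint, dropped)
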