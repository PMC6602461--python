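"""Synthetic test-surface generator: universes, nested term hierarchies,
mapping/ortholog tables, gene intervals, and queries with planted signal.

The term hierarchy is built top-down as nested subsets — every child term
is a random subset of its parent — which reproduces the key statistical
feature of real ontology annotations that motivates overlap-aware multiple
testing: strongly correlated, partially redundant terms. Because the
containment structure is known by construction, layout and correction
behaviour can be checked analytically. All randomness flows through one
seeded generator per artifact; identical specs and seeds reproduce every
artifact byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotation import (
    GeneUniverse,
    Term,
    TermStore,
    bitset_from_positions,
    write_gmt,
)
from .enrich import Query
from .idmap import GeneIntervals, MappingTable, OrthologTable

__all__ = ["FixtureSpec", "Fixture", "generate_fixture", "generate_query", "write_fixture_files"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic annotation world.

    ``depth``/``branching`` shape the nested-subset hierarchy (depth 1 means
    independent draws with no forced overlap); ``size_range`` bounds term
    sizes; ``sources`` are cycled across root subtrees.
    """

    N: int = 1000
    T: int = 50
    size_range: tuple[int, int] = (10, 100)
    depth: int = 3
    branching: int = 3
    sources: tuple[str, ...] = ("GO:BP", "PATH")
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.size_range
        if not (1 <= lo <= hi):
            raise ValueError("size_range must satisfy 1 <= min <= max")
        if hi > self.N:
            raise ValueError(f"size_range max {hi} exceeds universe size {self.N}")
        if self.T < 1 or self.depth < 1 or self.branching < 1:
            raise ValueError("T, depth and branching must be >= 1")


@dataclass(frozen=True)
class Fixture:
    universe: GeneUniverse
    store: TermStore
    parent_edges: dict[str, tuple[str, ...]] = field(default_factory=dict)
    mapping: MappingTable | None = None
    orthologs: OrthologTable | None = None
    intervals: GeneIntervals | None = None


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Generate the full synthetic test surface from a spec.

    Terms are laid out as root subtrees (breadth-first, child ⊂ parent)
    until ``T`` terms exist; aliases are emitted in three namespaces (plus
    gene names) with one deliberately ambiguous alias; orthologs are
    one-to-many for every tenth gene and absent for every seventh; gene
    intervals tile a single synthetic chromosome.
    """
    rng = np.random.default_rng(spec.seed)
    genes = tuple(f"G{i:06d}" for i in range(spec.N))
    universe = GeneUniverse.from_genes(genes)
    lo, hi = spec.size_range

    terms: list[Term] = []
    parent_edges: dict[str, tuple[str, ...]] = {}
    frontier: list[tuple[np.ndarray, str, int, str]] = []  # (members, tid, depth, source)
    tree_idx = 0
    while len(terms) < spec.T:
        if not frontier:
            source = spec.sources[tree_idx % len(spec.sources)]
            tree_idx += 1
            size = int(rng.integers(max(lo, (lo + hi) // 2), hi + 1))
            members = rng.choice(spec.N, size=size, replace=False)
            tid = f"T{len(terms):04d}"
            terms.append(_make_term(tid, source, members))
            frontier.append((members, tid, 1, source))
            continue
        members, parent_id, d, source = frontier.pop(0)
        if d >= spec.depth:
            continue
        for _ in range(spec.branching):
            if len(terms) >= spec.T:
                break
            upper = max(lo, int(len(members) * 0.7))
            size = int(rng.integers(lo, upper + 1)) if upper > lo else lo
            size = min(size, len(members))
            child = rng.choice(members, size=size, replace=False)
            tid = f"T{len(terms):04d}"
            terms.append(_make_term(tid, source, child, parent=parent_id))
            parent_edges[tid] = (parent_id,)
            frontier.append((child, tid, d + 1, source))
    store = TermStore(universe=universe, terms=tuple(terms))

    entries = []
    for i, g in enumerate(genes):
        entries.append((g, "ensg", g))  # reference ids resolve as themselves
        entries.append((f"sym{i}", "symbol", g))
        entries.append((f"{i}_probe_at", "probe", g))
        entries.append((f"ACC{i:06d}", "accession", g))
        entries.append((f"synthetic gene {i}", "name", g))
    # one deliberately ambiguous alias shared by the first two genes
    entries.append(("AMBIG1", "symbol", genes[0]))
    entries.append(("AMBIG1", "symbol", genes[1]))
    mapping = MappingTable.from_entries(entries)

    orth_entries = []
    for i, g in enumerate(genes):
        if i % 7 == 3:
            continue  # no ortholog
        orth_entries.append((g, "mmusculus", f"MUSG{i:06d}"))
        if i % 10 == 0:
            orth_entries.append((g, "mmusculus", f"MUSG{i:06d}b"))
    orthologs = OrthologTable(tuple(orth_entries))

    intervals = GeneIntervals(
        tuple(("chr1", i * 1000, i * 1000 + 800, g) for i, g in enumerate(genes))
    )
    return Fixture(universe, store, parent_edges, mapping, orthologs, intervals)


_EVIDENCE_CODES = ("IEA", "EXP", "IDA", "TAS")


def _make_term(tid: str, source: str, members: np.ndarray, parent: str | None = None) -> Term:
    # deterministic evidence codes keyed on gene position, cycling the GO-style set
    evidence = {
        f"G{int(p):06d}": _EVIDENCE_CODES[int(p) % len(_EVIDENCE_CODES)] for p in members
    }
    return Term(
        term_id=tid,
        name=f"synthetic term {tid}",
        source=source,
        members=bitset_from_positions(int(p) for p in members),
        parent_ids=(parent,) if parent else (),
        evidence=evidence,
    )


def generate_query(
    store: TermStore,
    planted_term: Term | str | None,
    f: float,
    n: int,
    ordered: bool = False,
    seed: int = 0,
) -> Query:
    """Draw a query of size ``n`` with a planted signal fraction ``f``.

    ``ceil(f*n)`` genes are sampled from the planted term and the remainder
    uniformly from its complement; ``f=0`` (or no planted term) gives a
    uniform null query. In ordered mode the planted genes concentrate at
    the front of the list with seed-controlled noise interleaving.
    """
    rng = np.random.default_rng(seed)
    N = len(store.universe)
    if n < 1 or n > N:
        raise ValueError(f"query size {n} outside [1, {N}]")
    if not 0 <= f <= 1:
        raise ValueError("signal fraction f must lie in [0, 1]")
    if isinstance(planted_term, str):
        planted_term = store.get(planted_term)
    if planted_term is None or f == 0:
        positions = rng.choice(N, size=n, replace=False)
        planted_mask = np.zeros(n, dtype=bool)
    else:
        members = np.fromiter(_bits(planted_term.members), dtype=int)
        m = math.ceil(f * n)
        if m > len(members):
            raise ValueError(
                f"ceil(f*n)={m} exceeds planted term size K={len(members)}"
            )
        complement = np.setdiff1d(np.arange(N), members, assume_unique=True)
        if n - m > len(complement):
            raise ValueError("not enough genes outside the planted term")
        sig = rng.choice(members, size=m, replace=False)
        noise = rng.choice(complement, size=n - m, replace=False)
        positions = np.concatenate([sig, noise])
        planted_mask = np.concatenate([np.ones(m, bool), np.zeros(n - m, bool)])
    if ordered:
        # planted genes get early rank keys, noise late; overlapping key
        # ranges interleave a few noise genes among the signal
        keys = np.where(
            planted_mask, rng.uniform(0.0, 0.35, n), rng.uniform(0.25, 1.0, n)
        )
        order = np.argsort(keys, kind="stable")
        positions = positions[order]
    else:
        positions = rng.permutation(positions)
    name = "null_query" if planted_mask.sum() == 0 else "planted_query"
    return Query(name=name, genes=tuple(int(p) for p in positions), ordered=ordered)


def _bits(bits: int):
    pos = 0
    while bits:
        tz = (bits & -bits).bit_length() - 1
        pos += tz
        yield pos
        bits >>= tz + 1
        pos += 1


def write_fixture_files(fixture: Fixture, out_dir: str | Path) -> dict[str, Path]:
    """Write the fixture as standard files usable directly as CLI inputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["gmt"] = out / "terms.gmt"
    with paths["gmt"].open("w") as fh:
        write_gmt(fixture.store, fh)

    paths["parents"] = out / "parents.tsv"
    with paths["parents"].open("w") as fh:
        fh.write("term_id\tparent_id\n")
        for child, parents in sorted(fixture.parent_edges.items()):
            for p in parents:
                fh.write(f"{child}\t{p}\n")

    if fixture.mapping is not None:
        paths["mapping"] = out / "mapping.tsv"
        with paths["mapping"].open("w") as fh:
            fh.write("alias\tnamespace\treference_id\n")
            for alias, ns, ref in fixture.mapping.entries:
                fh.write(f"{alias}\t{ns}\t{ref}\n")

    if fixture.orthologs is not None:
        paths["orthologs"] = out / "orthologs.tsv"
        with paths["orthologs"].open("w") as fh:
            fh.write("source_reference_id\ttarget_species\ttarget_reference_id\n")
            for s, sp, t in fixture.orthologs.entries:
                fh.write(f"{s}\t{sp}\t{t}\n")

    if fixture.intervals is not None:
        paths["genes_bed"] = out / "genes.bed"
        with paths["genes_bed"].open("w") as fh:
            for chrom, start, end, ref in fixture.intervals.records:
                fh.write(f"{chrom}\t{start}\t{end}\t{ref}\n")

    paths["background"] = out / "background.txt"
    with paths["background"].open("w") as fh:
        fh.write("\n".join(fixture.universe.genes) + "\n")
    return paths
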