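"""Bitset-backed gene-set annotation store.

Gene sets are read from GMT (Gene Matrix Transposed) files — tab-separated,
one set per line: ``set_id<TAB>description<TAB>gene1<TAB>gene2...`` — and
projected onto a :class:`GeneUniverse`, the background against which all
over-representation statistics are computed. Each term's membership is kept
as an arbitrary-precision integer bitmask over universe positions, so
intersection sizes (the ``k`` of the hypergeometric test) are single
``&``/``bit_count`` operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Iterator, Mapping, Sequence

__all__ = [
    "GeneUniverse",
    "Term",
    "TermStore",
    "GmtRecord",
    "GmtParseResult",
    "BuildReport",
    "parse_gmt",
    "write_gmt",
    "build_store",
    "restrict_to_background",
    "read_background",
    "bitset_from_positions",
    "positions_from_bitset",
]


def bitset_from_positions(positions: Iterable[int]) -> int:
    """Pack integer positions into a bitmask."""
    bits = 0
    for p in positions:
        bits |= 1 << p
    return bits


def positions_from_bitset(bits: int) -> Iterator[int]:
    """Yield the set positions of a bitmask in ascending order."""
    pos = 0
    while bits:
        tz = (bits & -bits).bit_length() - 1
        pos += tz
        yield pos
        bits >>= tz + 1
        pos += 1


@dataclass(frozen=True)
class GeneUniverse:
    """The background gene set: an ordered, indexed collection of identifiers.

    The universe defines ``N`` of the hypergeometric sample space and the
    bit positions every term bitmask refers to.
    """

    genes: tuple[str, ...]
    index: Mapping[str, int] = field(repr=False)

    @classmethod
    def from_genes(cls, genes: Iterable[str]) -> "GeneUniverse":
        ordered = tuple(genes)
        if not ordered:
            raise ValueError("universe must contain at least one gene")
        index = {g: i for i, g in enumerate(ordered)}
        if len(index) != len(ordered):
            seen: set[str] = set()
            dup = next(g for g in ordered if g in seen or seen.add(g))
            raise ValueError(f"duplicate gene identifier in universe: {dup!r}")
        return cls(genes=ordered, index=index)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.index

    def position(self, gene: str) -> int:
        return self.index[gene]


@dataclass(frozen=True)
class Term:
    """A functional term (gene set) projected onto a universe.

    ``members`` is a bitmask over universe positions; its popcount is the
    term size ``K`` within the active background.
    """

    term_id: str
    name: str
    source: str
    members: int
    parent_ids: tuple[str, ...] = ()
    evidence: Mapping[str, str] | None = None

    @property
    def size(self) -> int:
        return self.members.bit_count()

    def member_genes(self, universe: GeneUniverse) -> tuple[str, ...]:
        return tuple(universe.genes[p] for p in positions_from_bitset(self.members))


@dataclass(frozen=True)
class TermStore:
    """A source-tagged collection of terms over a shared universe."""

    universe: GeneUniverse
    terms: tuple[Term, ...]

    def __post_init__(self) -> None:
        keys = {(t.source, t.term_id) for t in self.terms}
        if len(keys) != len(self.terms):
            raise ValueError("duplicate (source, term_id) in store")

    @property
    def sources(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for t in self.terms:
            seen.setdefault(t.source, None)
        return tuple(seen)

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self) -> Iterator[Term]:
        return iter(self.terms)

    def get(self, term_id: str) -> Term:
        for t in self.terms:
            if t.term_id == term_id:
                return t
        raise KeyError(term_id)


@dataclass(frozen=True)
class GmtRecord:
    set_id: str
    description: str
    members: tuple[str, ...]


@dataclass(frozen=True)
class GmtParseResult:
    records: tuple[GmtRecord, ...]
    skipped_lines: int


def parse_gmt(stream: IO[str] | Iterable[str]) -> GmtParseResult:
    """Parse a GMT stream into raw gene-set records.

    Lines with fewer than three tab-separated fields are skipped and
    counted; repeated member tokens within a line are deduplicated keeping
    the first occurrence. Raises on an empty stream or a duplicated set id.
    """
    records: list[GmtRecord] = []
    seen_ids: set[str] = set()
    skipped = 0
    for line in stream:
        line = line.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            skipped += 1
            continue
        set_id, description, *tokens = fields
        if set_id in seen_ids:
            raise ValueError(f"duplicate gene set id: {set_id!r}")
        seen_ids.add(set_id)
        members = tuple(dict.fromkeys(t for t in tokens if t))
        records.append(GmtRecord(set_id, description, members))
    if not records and skipped == 0:
        raise ValueError("no gene sets")
    if not records:
        raise ValueError(f"no gene sets (all {skipped} lines malformed)")
    return GmtParseResult(tuple(records), skipped)


def write_gmt(store: TermStore, stream: IO[str]) -> int:
    """Serialize a store back to GMT; returns the count of omitted empty terms.

    Members are written in universe index order, so parse→write→parse is an
    identity on ids, descriptions and member sets.
    """
    if not store.terms:
        raise ValueError("cannot write an empty store")
    omitted = 0
    for term in store.terms:
        if term.members == 0:
            omitted += 1
            continue
        genes = term.member_genes(store.universe)
        stream.write("\t".join((term.term_id, term.name, *genes)) + "\n")
    return omitted


@dataclass(frozen=True)
class BuildReport:
    """Per-term accounting of build_store's projection and filtering."""

    dropped_tokens: Mapping[str, tuple[str, ...]]
    excluded_terms: tuple[str, ...]
    projected_sizes: Mapping[str, int]

    @property
    def total_projected_size(self) -> int:
        return sum(self.projected_sizes.values())


def build_store(
    records: Iterable[GmtRecord],
    universe: GeneUniverse,
    min_term_size: int = 1,
    max_term_size: int | None = None,
    source: str = "CUSTOM",
    parent_edges: Mapping[str, Sequence[str]] | None = None,
    evidence: Mapping[str, Mapping[str, str]] | None = None,
) -> tuple[TermStore, BuildReport]:
    """Project raw GMT records onto a universe and apply the term-size filter.

    Member tokens absent from the universe are dropped (reported per term);
    terms whose projected size falls outside ``[min_term_size,
    max_term_size]`` are excluded. Tokens are matched case-sensitively:
    identifier normalization happens upstream in :mod:`overrep.idmap`.
    """
    if min_term_size < 1:
        raise ValueError("min_term_size must be >= 1")
    if max_term_size is not None and max_term_size < min_term_size:
        raise ValueError("max_term_size must be >= min_term_size")
    terms: list[Term] = []
    dropped: dict[str, tuple[str, ...]] = {}
    excluded: list[str] = []
    sizes: dict[str, int] = {}
    for rec in records:
        positions = []
        missing = []
        for tok in rec.members:
            pos = universe.index.get(tok)
            if pos is None:
                missing.append(tok)
            else:
                positions.append(pos)
        if missing:
            dropped[rec.set_id] = tuple(missing)
        size = len(positions)
        if size < min_term_size or (max_term_size is not None and size > max_term_size):
            excluded.append(rec.set_id)
            continue
        sizes[rec.set_id] = size
        terms.append(
            Term(
                term_id=rec.set_id,
                name=rec.description,
                source=source,
                members=bitset_from_positions(positions),
                parent_ids=tuple(parent_edges.get(rec.set_id, ())) if parent_edges else (),
                evidence=dict(evidence[rec.set_id]) if evidence and rec.set_id in evidence else None,
            )
        )
    if not terms:
        raise ValueError("all terms were filtered out by the size filter / projection")
    store = TermStore(universe=universe, terms=tuple(terms))
    return store, BuildReport(dropped, tuple(excluded), sizes)


def restrict_to_background(store: TermStore, background: Iterable[str]) -> TermStore:
    """Re-project a store onto the intersection of its universe with a custom background.

    The new universe keeps the original gene order; term bitmasks, and hence
    every N and K downstream, are recomputed. Terms left empty by the
    projection are dropped. Idempotent for a fixed background.
    """
    requested = set(background)
    kept = [g for g in store.universe.genes if g in requested]
    if not kept:
        unmatched = sorted(requested)[:5]
        raise ValueError(
            "background does not intersect the universe; "
            f"sample of unmatched tokens: {unmatched}"
        )
    new_universe = GeneUniverse.from_genes(kept)
    old_pos = [store.universe.index[g] for g in kept]
    terms: list[Term] = []
    for term in store.terms:
        new_members = bitset_from_positions(
            i for i, p in enumerate(old_pos) if term.members >> p & 1
        )
        if new_members == 0:
            continue
        terms.append(replace(term, members=new_members))
    return TermStore(universe=new_universe, terms=tuple(terms))


def read_background(stream: IO[str] | Iterable[str]) -> tuple[str, ...]:
    """Read a plain-text background list: one identifier per line, '#' comments ignored."""
    out: dict[str, None] = {}
    for line in stream:
        line = line.split("#", 1)[0].strip()
        if line:
            out.setdefault(line, None)
    return tuple(out)
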