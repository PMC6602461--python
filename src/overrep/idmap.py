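"""Mixed-identifier resolution, namespace conversion, ortholog and interval mapping.

Every alias (gene symbol, probe id, accession, ...) is matched case-insensitively
against a reference identifier through a user-supplied TSV mapping table, so
queries may freely mix identifier types. Genomic intervals (BED, 0-based
half-open) are mapped to genes by coordinate overlap.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "MappingTable",
    "Resolution",
    "ResolveReport",
    "OrthologTable",
    "GeneIntervals",
    "load_mapping_table",
    "load_ortholog_table",
    "load_gene_intervals",
    "parse_bed",
    "resolve_tokens",
    "convert_ids",
    "map_orthologs",
    "intervals_to_genes",
    "INTERVAL_TOKEN_RE",
]

#: Ensembl-style region token, 1-based inclusive, e.g. ``chr3:1200-5000``.
INTERVAL_TOKEN_RE = re.compile(r"^([A-Za-z0-9_.]+):(\d+)-(\d+)$")

#: Namespace whose aliases are treated as human-readable gene names/descriptions.
NAME_NAMESPACE = "name"


@dataclass(frozen=True)
class MappingTable:
    """Alias → reference-id correspondences, indexed by case-folded alias.

    An alias may map to several reference ids (possibly through different
    namespaces); that ambiguity is preserved, never collapsed here.
    """

    entries: tuple[tuple[str, str, str], ...]  # (alias, namespace, reference_id)
    by_alias: Mapping[str, tuple[tuple[str, str, str], ...]] = field(repr=False)

    @classmethod
    def from_entries(cls, entries: Iterable[tuple[str, str, str]]) -> "MappingTable":
        uniq = tuple(dict.fromkeys(tuple(e) for e in entries))
        index: dict[str, list[tuple[str, str, str]]] = {}
        for e in uniq:
            index.setdefault(e[0].casefold(), []).append(e)
        return cls(entries=uniq, by_alias={k: tuple(v) for k, v in index.items()})

    @property
    def namespaces(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(ns for _, ns, _ in self.entries))

    def lookup(self, token: str) -> tuple[tuple[str, str, str], ...]:
        return self.by_alias.get(token.casefold(), ())

    def aliases_of(self, reference_id: str, namespace: str) -> tuple[str, ...]:
        return tuple(
            a for a, ns, ref in self.entries if ref == reference_id and ns == namespace
        )


def load_mapping_table(stream: IO[str] | str) -> MappingTable:
    """Load a TSV with columns ``alias``, ``namespace``, ``reference_id``."""
    df = pd.read_csv(stream, sep="\t", dtype=str)
    for col in ("alias", "namespace", "reference_id"):
        if col not in df.columns:
            raise ValueError(f"mapping table is missing required column {col!r}")
    if df.empty:
        raise ValueError("mapping table has no rows")
    return MappingTable.from_entries(
        df[["alias", "namespace", "reference_id"]].itertuples(index=False, name=None)
    )


@dataclass(frozen=True)
class Resolution:
    """Outcome of resolving one input token."""

    token: str
    status: str  # resolved | ambiguous | unresolved
    reference_ids: tuple[str, ...]
    chosen_namespace: str | None = None

    def __post_init__(self) -> None:
        if self.status == "resolved" and len(self.reference_ids) != 1:
            raise ValueError("resolved implies exactly one reference id")
        if self.status == "ambiguous" and len(self.reference_ids) < 2:
            raise ValueError("ambiguous implies at least two reference ids")
        if self.status == "unresolved" and self.reference_ids:
            raise ValueError("unresolved implies no reference ids")


@dataclass(frozen=True)
class ResolveReport:
    resolutions: tuple[Resolution, ...]
    duplicate_count: int

    @property
    def resolved_ids(self) -> tuple[str, ...]:
        """Reference ids of unambiguously resolved tokens, input order, deduplicated."""
        out: dict[str, None] = {}
        for r in self.resolutions:
            if r.status == "resolved":
                out.setdefault(r.reference_ids[0], None)
        return tuple(out)

    def count(self, status: str) -> int:
        return sum(1 for r in self.resolutions if r.status == status)


def resolve_tokens(
    tokens: Sequence[str],
    table: MappingTable,
    take_first: bool = False,
) -> ResolveReport:
    """Resolve mixed-type tokens to reference ids.

    Lookup is case-insensitive; input order is preserved; duplicate tokens
    (after case-folding) collapse to their first occurrence and are counted.
    A token matching several reference ids is reported ``ambiguous`` unless
    ``take_first`` is set, in which case the lexicographically smallest
    reference id is chosen.
    """
    if not tokens:
        raise ValueError("no tokens to resolve")
    seen: set[str] = set()
    duplicates = 0
    out: list[Resolution] = []
    for tok in tokens:
        key = tok.casefold()
        if key in seen:
            duplicates += 1
            continue
        seen.add(key)
        hits = table.lookup(tok)
        refs = tuple(sorted({ref for _, _, ref in hits}))
        if not refs:
            out.append(Resolution(tok, "unresolved", ()))
        elif len(refs) == 1:
            ns = sorted({ns for _, ns, ref in hits if ref == refs[0]})[0]
            out.append(Resolution(tok, "resolved", refs, ns))
        elif take_first:
            ns = sorted({ns for _, ns, ref in hits if ref == refs[0]})[0]
            out.append(Resolution(tok, "resolved", (refs[0],), ns))
        else:
            out.append(Resolution(tok, "ambiguous", refs))
    return ResolveReport(tuple(out), duplicates)


def convert_ids(
    tokens: Sequence[str],
    table: MappingTable,
    target_namespace: str,
) -> pd.DataFrame:
    """Convert tokens to a target namespace through the reference ids.

    Returns one row per (token, reference_id, target_alias) combination.
    Unresolved tokens and references without a target alias emit rows with
    empty mapping fields. The ``name`` column carries the alias from the
    ``name`` namespace when present.
    """
    if target_namespace not in table.namespaces:
        raise ValueError(f"unknown target namespace {target_namespace!r}")
    rows: list[tuple[str, str, str, str]] = []
    for tok in tokens:
        hits = table.lookup(tok)
        refs = sorted({ref for _, _, ref in hits})
        if not refs:
            rows.append((tok, "", "", ""))
            continue
        for ref in refs:
            names = table.aliases_of(ref, NAME_NAMESPACE)
            name = names[0] if names else ""
            aliases = table.aliases_of(ref, target_namespace)
            if not aliases:
                rows.append((tok, ref, "", name))
            else:
                for alias in aliases:
                    rows.append((tok, ref, alias, name))
    return pd.DataFrame(rows, columns=["token", "reference_id", "target_alias", "name"])


@dataclass(frozen=True)
class OrthologTable:
    """Reference-id → reference-id ortholog pairs per target species; one-to-many allowed."""

    entries: tuple[tuple[str, str, str], ...]  # (source_ref, target_species, target_ref)

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(sp for _, sp, _ in self.entries))

    def targets(self, source_ref: str, species: str) -> tuple[str, ...]:
        return tuple(
            t for s, sp, t in self.entries if s == source_ref and sp == species
        )


def load_ortholog_table(stream: IO[str] | str) -> OrthologTable:
    df = pd.read_csv(stream, sep="\t", dtype=str)
    for col in ("source_reference_id", "target_species", "target_reference_id"):
        if col not in df.columns:
            raise ValueError(f"ortholog table is missing required column {col!r}")
    if df.empty:
        raise ValueError("ortholog table has no rows")
    entries = tuple(
        dict.fromkeys(
            df[["source_reference_id", "target_species", "target_reference_id"]]
            .itertuples(index=False, name=None)
        )
    )
    return OrthologTable(entries)


def map_orthologs(
    tokens: Sequence[str],
    table: MappingTable,
    orth: OrthologTable,
    target_species: str,
) -> pd.DataFrame:
    """Two-step ortholog mapping: token → reference id → target-species reference id.

    One row per mapping pair; a resolved gene without an ortholog emits a row
    with an empty target, and an unresolved token a row with both mapping
    fields empty.
    """
    if target_species not in orth.species:
        raise ValueError(f"unknown target species {target_species!r}")
    rows: list[tuple[str, str, str]] = []
    for tok in tokens:
        refs = sorted({ref for _, _, ref in table.lookup(tok)})
        if not refs:
            rows.append((tok, "", ""))
            continue
        for ref in refs:
            targets = orth.targets(ref, target_species)
            if not targets:
                rows.append((tok, ref, ""))
            else:
                for t in targets:
                    rows.append((tok, ref, t))
    return pd.DataFrame(
        rows, columns=["token", "source_reference_id", "target_reference_id"]
    )


@dataclass(frozen=True)
class GeneIntervals:
    """Gene coordinates, 0-based half-open, chromosome labels opaque."""

    records: tuple[tuple[str, int, int, str], ...]  # (chrom, start, end, reference_id)

    def __post_init__(self) -> None:
        for chrom, start, end, ref in self.records:
            if start < 0 or end <= start:
                raise ValueError(f"invalid interval {chrom}:{start}-{end} for {ref}")

    def trees(self) -> Mapping[str, IntervalTree]:
        by_chrom: dict[str, IntervalTree] = {}
        for chrom, start, end, ref in self.records:
            by_chrom.setdefault(chrom, IntervalTree()).addi(start, end, ref)
        return by_chrom


def load_gene_intervals(stream: IO[str] | str, one_based: bool = False) -> GeneIntervals:
    """Load a gene coordinate table: ``chrom  start  end  reference_id``.

    ``one_based=True`` reads GFF-like 1-based inclusive coordinates and
    normalizes them to the internal 0-based half-open convention.
    """
    records = []
    for chrom, start, end, ref in parse_bed(stream, n_fields=4):
        if one_based:
            start, end = start - 1, end  # [s,e] 1-based incl -> [s-1,e) 0-based
        records.append((chrom, start, end, ref))
    return GeneIntervals(tuple(records))


def parse_bed(stream: IO[str] | Iterable[str], n_fields: int = 3) -> list[tuple]:
    """Parse BED-like lines into (chrom, start, end[, name]) tuples.

    Raises on ``start >= end`` naming the offending line.
    """
    if isinstance(stream, str):
        stream = stream.splitlines()
    out = []
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < n_fields:
            raise ValueError(f"line {lineno}: expected >= {n_fields} fields")
        chrom, start_s, end_s = fields[0], fields[1], fields[2]
        start, end = int(start_s), int(end_s)
        if start >= end:
            raise ValueError(f"line {lineno}: start >= end ({chrom}:{start}-{end})")
        if n_fields >= 4:
            out.append((chrom, start, end, fields[3]))
        else:
            out.append((chrom, start, end))
    return out


def intervals_to_genes(
    query_intervals: Sequence[tuple[str, int, int]],
    genes: GeneIntervals,
) -> tuple[tuple[str, ...], list[dict]]:
    """Map query intervals (0-based half-open) to overlapping genes.

    A gene is returned iff it shares at least one base with a query interval
    on the same chromosome. The result is deduplicated and ordered by the
    first matching query interval (genes within one interval sorted by start
    coordinate, then id, for determinism). A per-interval report lists the
    hits of each query interval.
    """
    trees = genes.trees()
    seen: dict[str, None] = {}
    report: list[dict] = []
    for chrom, start, end in query_intervals:
        if start >= end:
            raise ValueError(f"invalid query interval {chrom}:{start}-{end}")
        tree = trees.get(chrom)
        hits = sorted(tree.overlap(start, end), key=lambda iv: (iv.begin, iv.data)) if tree else []
        ids = [iv.data for iv in hits]
        report.append({"chrom": chrom, "start": start, "end": end, "genes": tuple(ids)})
        for ref in ids:
            seen.setdefault(ref, None)
    return tuple(seen), report
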