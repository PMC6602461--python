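"""Deterministic result rendering: Manhattan layout, CSV/GEM tables, PNG.

The Manhattan plot places every term of the store at a fixed x position —
sources grouped in a configured order, and terms within a source arranged
so that members of the same annotation subtree sit next to each other
(depth-first over the parent graph). Because the positions depend only on
the store, the parent edges and the source order — never on p-values — the
same term lands at the same x across queries, which is what makes
side-by-side comparison of several query plots meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import IO, Mapping, Sequence

import pandas as pd

from .annotation import TermStore
from .enrich import EnrichmentRecord

__all__ = [
    "LayoutPoint",
    "ManhattanLayout",
    "term_order",
    "layout_manhattan",
    "write_results_csv",
    "write_gem",
    "write_layout_tsv",
    "render_manhattan_png",
]


@dataclass(frozen=True)
class LayoutPoint:
    term_id: str
    x: float
    y: float  # -log10(p_adj)
    radius: float
    color_group: str  # source tag
    significant: bool


@dataclass(frozen=True)
class ManhattanLayout:
    points: tuple[LayoutPoint, ...]
    source_blocks: tuple[tuple[str, float, float], ...]  # (source, x_start, x_end)


def term_order(
    store: TermStore,
    parent_edges: Mapping[str, Sequence[str]] | None = None,
    source_order: Sequence[str] | None = None,
) -> list[str]:
    """Fixed term ordering: source blocks, subtree-adjacent within each block.

    With parent edges, each source block is a depth-first traversal of the
    parent graph (children directly after their parents, siblings in
    lexicographic term_id order); without edges, plain lexicographic order.
    Raises on cyclic parent edges, naming a cycle member.
    """
    sources = list(source_order) if source_order else sorted(store.sources)
    edges = dict(parent_edges) if parent_edges else {
        t.term_id: list(t.parent_ids) for t in store.terms if t.parent_ids
    }
    ordered: list[str] = []
    for src in sources:
        ids = sorted(t.term_id for t in store.terms if t.source == src)
        id_set = set(ids)
        children: dict[str, list[str]] = {i: [] for i in ids}
        roots = []
        for tid in ids:
            parents = [p for p in edges.get(tid, ()) if p in id_set]
            if parents:
                children[sorted(parents)[0]].append(tid)
            else:
                roots.append(tid)
        _check_acyclic(ids, edges, id_set)
        stack = list(reversed(roots))
        seen: set[str] = set()
        while stack:
            tid = stack.pop()
            if tid in seen:
                continue
            seen.add(tid)
            ordered.append(tid)
            stack.extend(reversed(sorted(children[tid])))
        # cycles unreachable from any root would be caught above; keep order total
        for tid in ids:
            if tid not in seen:
                ordered.append(tid)
    return ordered


def _check_acyclic(ids, edges, id_set) -> None:
    WHITE, GREY, BLACK = 0, 1, 2
    color = {i: WHITE for i in ids}
    for start in ids:
        if color[start] != WHITE:
            continue
        stack = [(start, iter([p for p in edges.get(start, ()) if p in id_set]))]
        color[start] = GREY
        while stack:
            node, it = stack[-1]
            advanced = False
            for parent in it:
                if color[parent] == GREY:
                    raise ValueError(f"cyclic parent edges involving term {parent!r}")
                if color[parent] == WHITE:
                    color[parent] = GREY
                    stack.append(
                        (parent, iter([p for p in edges.get(parent, ()) if p in id_set]))
                    )
                    advanced = True
                    break
            if not advanced:
                color[node] = BLACK
                stack.pop()


def layout_manhattan(
    records: Sequence[EnrichmentRecord],
    store: TermStore,
    parent_edges: Mapping[str, Sequence[str]] | None = None,
    source_order: Sequence[str] | None = None,
    r_min: float = 2.0,
    r_max: float = 12.0,
) -> ManhattanLayout:
    """Compute the Manhattan layout for one query's records.

    x = the term's rank in the store-wide fixed ordering; y = -log10(p_adj);
    radius = sqrt(K) affinely scaled into [r_min, r_max] over the store's
    term-size range, so marker area grows linearly with term size.
    """
    names = {r.query_name for r in records}
    if len(names) > 1:
        raise ValueError("layout_manhattan expects records from a single query")
    order = term_order(store, parent_edges, source_order)
    rank = {tid: i for i, tid in enumerate(order)}
    sizes = [t.size for t in store.terms]
    smin, smax = math.sqrt(min(sizes)), math.sqrt(max(sizes))
    span = smax - smin

    def radius(K: int) -> float:
        if span == 0:
            return (r_min + r_max) / 2
        return r_min + (math.sqrt(K) - smin) / span * (r_max - r_min)

    points = tuple(
        LayoutPoint(
            term_id=r.term_id,
            x=float(rank[r.term_id]),
            y=-math.log10(r.p_adj),
            radius=radius(r.K),
            color_group=r.source,
            significant=r.significant,
        )
        for r in sorted(records, key=lambda r: rank[r.term_id])
    )
    blocks = []
    src_of = {t.term_id: t.source for t in store.terms}
    for tid in order:
        src = src_of[tid]
        if blocks and blocks[-1][0] == src:
            blocks[-1] = (src, blocks[-1][1], float(rank[tid]))
        else:
            blocks.append((src, float(rank[tid]), float(rank[tid])))
    return ManhattanLayout(points=points, source_blocks=tuple(blocks))


CSV_COLUMNS = [
    "query",
    "source",
    "term_id",
    "term_name",
    "term_size",
    "query_size",
    "intersection_size",
    "p_adj",
    "prefix_length",
    "intersecting_genes",
    "evidence",
]


def write_results_csv(
    records: Sequence[EnrichmentRecord],
    stream: IO[str],
    order: Sequence[str] | None = None,
) -> None:
    """Write the results table as CSV.

    Single-query records produce the long format with intersecting genes
    and evidence codes; records from several queries produce the joint wide
    format with one adjusted-p column per query, restricted to terms
    significant in at least one query. Row order follows ``order`` (a term
    ordering, e.g. from :func:`term_order`) when given, else source then
    term_id — i.e. the Manhattan x order.
    """
    if not records:
        raise ValueError("no records to write")
    queries = list(dict.fromkeys(r.query_name for r in records))
    key = _row_key(order)
    if len(queries) == 1:
        rows = [
            {
                "query": r.query_name,
                "source": r.source,
                "term_id": r.term_id,
                "term_name": r.term_name,
                "term_size": r.K,
                "query_size": r.n,
                "intersection_size": r.k,
                "p_adj": r.p_adj,
                "prefix_length": "" if r.prefix_length is None else r.prefix_length,
                "intersecting_genes": ";".join(r.intersection_genes),
                "evidence": ";".join(r.evidence),
            }
            for r in sorted(records, key=key)
        ]
        df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    else:
        by_term: dict[str, dict[str, EnrichmentRecord]] = {}
        for r in records:
            by_term.setdefault(r.term_id, {})[r.query_name] = r
        keep = [
            tid
            for tid, recs in by_term.items()
            if any(r.significant for r in recs.values())
        ]
        proto = {tid: next(iter(v.values())) for tid, v in by_term.items()}
        keep.sort(key=lambda tid: key(proto[tid]))
        rows = []
        for tid in keep:
            r0 = proto[tid]
            row = {
                "source": r0.source,
                "term_id": tid,
                "term_name": r0.term_name,
                "term_size": r0.K,
            }
            for q in queries:
                rec = by_term[tid].get(q)
                row[f"p_adj_{q}"] = "" if rec is None else rec.p_adj
            rows.append(row)
        df = pd.DataFrame(
            rows,
            columns=["source", "term_id", "term_name", "term_size"]
            + [f"p_adj_{q}" for q in queries],
        )
    df.to_csv(stream, index=False, lineterminator="\n")


def _row_key(order: Sequence[str] | None):
    if order is None:
        return lambda r: (r.source, r.term_id)
    rank = {tid: i for i, tid in enumerate(order)}
    return lambda r: (rank.get(r.term_id, len(rank)), r.term_id)


def write_gem(
    records: Sequence[EnrichmentRecord],
    stream: IO[str],
    order: Sequence[str] | None = None,
) -> None:
    """Write significant single-query records in the generic enrichment-map
    (GEM) dialect consumed by Cytoscape EnrichmentMap.

    Tab-separated, header ``GO.ID Description p.Val FDR Phenotype Genes``;
    both p columns carry the adjusted p-value, Phenotype is ``+1``, genes
    are comma-joined in universe index order.
    """
    queries = {r.query_name for r in records}
    if len(queries) > 1:
        raise ValueError("GEM export is defined for single-query records")
    stream.write("GO.ID\tDescription\tp.Val\tFDR\tPhenotype\tGenes\n")
    key = _row_key(order)
    for r in sorted((r for r in records if r.significant), key=key):
        stream.write(
            f"{r.term_id}\t{r.term_name}\t{r.p_adj}\t{r.p_adj}\t+1\t"
            + ",".join(r.intersection_genes)
            + "\n"
        )


def write_layout_tsv(layout: ManhattanLayout, stream: IO[str]) -> None:
    """Serialize a layout: one row per point, then the source blocks."""
    stream.write("term_id\tx\ty\tradius\tsource\tsignificant\n")
    for p in layout.points:
        stream.write(
            f"{p.term_id}\t{p.x}\t{p.y}\t{p.radius}\t{p.color_group}\t"
            f"{int(p.significant)}\n"
        )
    stream.write("#source\tx_start\tx_end\n")
    for src, x0, x1 in layout.source_blocks:
        stream.write(f"#{src}\t{x0}\t{x1}\n")


def render_manhattan_png(
    layout: ManhattanLayout,
    target,
    excluded_sources: Sequence[str] = (),
    y_cap: float = 16.0,
    title: str | None = None,
) -> None:
    """Render the layout as a static PNG.

    Marker fill follows a viridis ramp on capped -log10(p_adj) — yellow for
    insignificant terms through dark blue for the smallest p-values;
    insignificant points are additionally drawn lighter, and blocks of
    sources excluded from the analysis are shaded grey.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if not layout.points:
        raise ValueError("cannot render an empty layout")
    fig, ax = plt.subplots(figsize=(10, 4), dpi=150)
    cmap = matplotlib.colormaps["viridis"]
    for p in layout.points:
        y = min(p.y, y_cap)
        t = min(y / y_cap, 1.0)
        color = cmap(1.0 - t)  # yellow (insignificant) -> dark blue (tiny p)
        ax.scatter(
            p.x,
            y,
            s=p.radius**2,
            color=color,
            alpha=1.0 if p.significant else 0.35,
            linewidths=0,
        )
    for src, x0, x1 in layout.source_blocks:
        if src in excluded_sources:
            ax.axvspan(x0 - 0.5, x1 + 0.5, color="0.8", zorder=0)
        ax.annotate(
            src,
            ((x0 + x1) / 2, -0.08),
            xycoords=("data", "axes fraction"),
            ha="center",
            fontsize=8,
        )
    ax.set_ylabel(r"$-\log_{10}(p_{\mathrm{adj}})$")
    ax.set_xticks([])
    ax.set_ylim(bottom=0)
    if title:
        ax.set_title(title)
    fig.savefig(target, format="png")
    plt.close(fig)
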