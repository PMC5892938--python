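"""Graph encodings of sequence/structure records.

Two base representations:

* the **complete graph** — one node per nucleotide labeled by its base, with
  backbone (``bb``) edges between consecutive positions and base-pair (``bp``)
  edges between paired positions;
* the **bulge graph** — one node per structural element after collapsing the
  structure into stems (``s``), hairpin loops (``h``), internal loops/bulges
  (``i``), multiloop/junction strands (``m``), and 5'/3' single-stranded
  tails (``f``/``t``).

Eleven transformation options combine these, attaching nucleotide-level
sequence information only within chosen structural contexts, so that the
kernel can be focused on the features a given RNA-binding domain is expected
to read.

Node ids are tuples: ``("nt", position)`` for nucleotide nodes, ``("el", k)``
for element nodes, ``("hy", k)`` for abstract hypergraph nodes.  This makes
coarser options' graphs literal subgraphs of richer ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .errors import UnknownOption
from .seqstruct import SeqStruct, parse_dotbracket, PairTable

#: element type letters
STEM, HAIRPIN, INTERNAL, MULTI, FIVE_TAIL, THREE_TAIL = "s", "h", "i", "m", "f", "t"


@dataclass(frozen=True)
class Element:
    idx: int
    kind: str  # one of s,h,i,m,f,t
    positions: tuple[int, ...]


@dataclass(frozen=True)
class ElementDecomposition:
    """Partition of sequence positions into structural elements plus
    backbone-contiguity adjacency between elements."""

    elements: tuple[Element, ...]
    adjacency: tuple[tuple[int, int], ...]  # element-index pairs, idx_a < idx_b

    def kind_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.elements:
            out[e.kind] = out.get(e.kind, 0) + 1
        return out

    def owner_of(self) -> dict[int, int]:
        """Map sequence position -> element index."""
        owner = {}
        for e in self.elements:
            for p in e.positions:
                owner[p] = e.idx
        return owner


def build_complete_graph(ss: SeqStruct) -> nx.Graph:
    """Per-nucleotide graph with backbone and base-pair edges."""
    pt = parse_dotbracket(ss.struct)
    g = nx.Graph()
    for i, base in enumerate(ss.seq):
        g.add_node(("nt", i), label=base)
    for i in range(len(ss.seq) - 1):
        g.add_edge(("nt", i), ("nt", i + 1), label="bb")
    for i, j in pt.pair_list():
        g.add_edge(("nt", i), ("nt", j), label="bp")
    return g


def _stems(pt: PairTable) -> list[list[tuple[int, int]]]:
    """Maximal stacks of pairs uninterrupted by unpaired bases on either side."""
    pairs = pt.pair_list()
    pairset = set(pairs)
    stems = []
    seen = set()
    for p in pairs:
        if p in seen:
            continue
        stem = [p]
        seen.add(p)
        i, j = p
        while (i + 1, j - 1) in pairset:
            i, j = i + 1, j - 1
            stem.append((i, j))
            seen.add((i, j))
        stems.append(stem)
    # a stem started mid-stack would have been absorbed: ensure starts are
    # stack-maximal (predecessor (i-1, j+1) not a pair)
    return [s for s in stems if (s[0][0] - 1, s[0][1] + 1) not in pairset]


def _enclosing_pair(pt: PairTable, a: int, b: int):
    """Innermost pair (i, j) with i < a and j > b, or None."""
    for p in range(a - 1, -1, -1):
        if pt.is_paired(p) and pt.partner(p) > b:
            return (p, pt.partner(p))
    return None


def decompose_elements(ss: SeqStruct) -> ElementDecomposition:
    """Collapse the structure into elements.

    Each maximal stack of pairs is one ``s`` element (any intervening
    unpaired base, even on one side only, splits stems).  Each maximal run of
    consecutive unpaired positions is one loop element, typed by its
    enclosing loop: hairpin, internal/bulge, multiloop/junction strand, or a
    5'/3' tail.  A fully unpaired structure is a single 3' tail by
    convention.  Elements are adjacent iff they contain consecutive
    positions, which keeps the element graph connected.
    """
    pt = parse_dotbracket(ss.struct)
    n = pt.n
    elements: list[Element] = []

    def add(kind: str, positions):
        elements.append(Element(idx=len(elements), kind=kind, positions=tuple(positions)))

    if pt.n_pairs == 0:
        if n:
            add(THREE_TAIL, range(n))
        return ElementDecomposition(tuple(elements), ())

    for stem in _stems(pt):
        pos = sorted({p for pair in stem for p in pair})
        add(STEM, pos)

    # maximal unpaired runs
    run: list[int] = []
    for p in range(n + 1):
        if p < n and not pt.is_paired(p):
            run.append(p)
        elif run:
            enc = _enclosing_pair(pt, run[0], run[-1])
            if enc is None:
                if not any(pt.is_paired(q) for q in range(0, run[0])):
                    kind = FIVE_TAIL
                elif not any(pt.is_paired(q) for q in range(run[-1] + 1, n)):
                    kind = THREE_TAIL
                else:
                    kind = MULTI  # external strand between outermost stems
            else:
                kind = _loop_kind_from_enclosing(pt, enc)
            add(kind, run)
            run = []

    elements.sort(key=lambda e: e.positions[0])
    elements = [Element(idx=k, kind=e.kind, positions=e.positions) for k, e in enumerate(elements)]

    owner = {}
    for e in elements:
        for p in e.positions:
            owner[p] = e.idx
    adj = set()
    for p in range(n - 1):
        a, b = owner[p], owner[p + 1]
        if a != b:
            adj.add((min(a, b), max(a, b)))
    return ElementDecomposition(tuple(elements), tuple(sorted(adj)))


def _loop_kind_from_enclosing(pt: PairTable, enclosing: tuple[int, int]) -> str:
    i, j = enclosing
    children = 0
    p = i + 1
    while p < j:
        if pt.is_paired(p) and pt.partner(p) > p:
            children += 1
            p = pt.partner(p) + 1
        else:
            p += 1
    if children == 0:
        return HAIRPIN
    if children == 1:
        return INTERNAL
    return MULTI


def build_bulge_graph(ss: SeqStruct) -> nx.Graph:
    """Element-level graph: one node per element, labeled by type and size.

    Labels carry the member count (e.g. ``s10``, ``h4``) so that the kernel
    can distinguish a 5-bp stem-loop from a 7-bp one even where all the
    nucleotide-level sequence is masked; element size is the coarsest
    structural feature an RNA-binding footprint is sensitive to.
    """
    dec = decompose_elements(ss)
    g = nx.Graph()
    for e in dec.elements:
        g.add_node(("el", e.idx), label=f"{e.kind}{len(e.positions)}")
    for a, b in dec.adjacency:
        g.add_edge(("el", a), ("el", b), label="el")
    return g


#: which element kinds carry nucleotide nodes under options 4-9
_CONTEXT_BY_OPTION = {
    4: {HAIRPIN},
    5: {INTERNAL},
    6: {FIVE_TAIL, THREE_TAIL},
    7: {STEM},
    8: {HAIRPIN, INTERNAL},
    9: {HAIRPIN, INTERNAL, MULTI, FIVE_TAIL, THREE_TAIL},
    10: {STEM, HAIRPIN, INTERNAL, MULTI, FIVE_TAIL, THREE_TAIL},
}


def _attach_sequence(g: nx.Graph, ss: SeqStruct, dec: ElementDecomposition, kinds: set[str]) -> None:
    """Add nucleotide nodes for positions owned by elements of the given
    kinds, chained by bb edges (consecutive included positions) and joined to
    their owning element node by an ``in`` edge."""
    owner = dec.owner_of()
    kind_of = {e.idx: e.kind for e in dec.elements}
    included = [p for p in range(len(ss)) if kind_of[owner[p]] in kinds]
    for p in included:
        g.add_node(("nt", p), label=ss.seq[p])
        g.add_edge(("nt", p), ("el", owner[p]), label="in")
    inc = set(included)
    for p in included:
        if p + 1 in inc:
            g.add_edge(("nt", p), ("nt", p + 1), label="bb")


def _hypergraph_overlay(g: nx.Graph, ss: SeqStruct, dec: ElementDecomposition) -> None:
    """Abstract annotation overlay: one node per contiguous single-stranded
    stretch and per stem strand-side, each linked to its member nucleotides."""
    k = 0
    for e in dec.elements:
        if e.kind == STEM:
            # two strand sides: opening side and closing side
            half = len(e.positions) // 2
            sides = [e.positions[:half], e.positions[half:]]
        else:
            sides = [e.positions]
        for side in sides:
            node = ("hy", k)
            g.add_node(node, label=e.kind)
            for p in side:
                g.add_edge(node, ("nt", p), label="in")
            k += 1


def transform(ss: SeqStruct, option: int) -> nx.Graph:
    """Build the graph for one of the 11 transformation options.

    1.  complete graph + abstract annotation overlay (GraphProt-like)
    2.  complete graph + bulge graph
    3.  bulge graph only
    4.  bulge graph + sequence in hairpin loops
    5.  bulge graph + sequence in internal loops and bulges
    6.  bulge graph + sequence in external (tail) regions
    7.  bulge graph + sequence in base-paired regions
    8.  bulge graph + sequence in hairpin + internal loops
    9.  bulge graph + sequence in all unpaired regions
    10. bulge graph + sequence everywhere
    11. bulge graph + complete graph with paired-position labels masked to "P"
    """
    if not isinstance(option, int) or option < 1 or option > 11:
        raise UnknownOption(f"graph transformation option must be 1..11, got {option!r}")

    if option == 1:
        g = build_complete_graph(ss)
        dec = decompose_elements(ss)
        _hypergraph_overlay(g, ss, dec)
        return g

    if option == 3:
        return build_bulge_graph(ss)

    dec = decompose_elements(ss)
    g = build_bulge_graph(ss)

    if option in (2, 11):
        pt = parse_dotbracket(ss.struct)
        owner = dec.owner_of()
        kind_of = {e.idx: e.kind for e in dec.elements}
        for i in range(len(ss)):
            if option == 11:
                # paired-region sequence is masked; unpaired bases keep their
                # structural context so that a loop A and a tail A stay
                # distinct features
                if pt.is_paired(i):
                    label = "P"
                else:
                    label = f"{ss.seq[i]}|{kind_of[owner[i]]}"
            else:
                label = ss.seq[i]
            g.add_node(("nt", i), label=label)
            g.add_edge(("nt", i), ("el", owner[i]), label="in")
        for i in range(len(ss) - 1):
            g.add_edge(("nt", i), ("nt", i + 1), label="bb")
        for i, j in pt.pair_list():
            g.add_edge(("nt", i), ("nt", j), label="bp")
        return g

    _attach_sequence(g, ss, dec, _CONTEXT_BY_OPTION[option])
    return g


def write_edgelist(g: nx.Graph, path) -> None:
    """Plain-text export: one node line per node, one edge line per edge."""
    with open(path, "w") as fh:
        for node, data in sorted(g.nodes(data=True)):
            fh.write(f"node\t{node[0]}:{node[1]}\t{data['label']}\n")
        for u, v, data in sorted(g.edges(data=True)):
            fh.write(f"edge\t{u[0]}:{u[1]}\t{v[0]}:{v[1]}\t{data['label']}\n")


def write_graphml(g: nx.Graph, path) -> None:
    """GraphML export with node/edge label attributes (for visualization)."""
    h = nx.relabel_nodes(g, {n: f"{n[0]}:{n[1]}" for n in g.nodes}, copy=True)
    nx.write_graphml(h, path)
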