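"""Fold an RNA, decompose it into structural elements, and build graphs.

Run:  python examples/01_fold_and_graphs.py
"""

from peakclust import SeqStruct, build_complete_graph, decompose_elements, fold, transform

seq = "GGGGAAACCAACCUGU"
struct = fold(seq)  # Nussinov maximum base pairing (WC + GU, min loop 3)
print(f"sequence   {seq}")
print(f"structure  {struct}   (built-in max-pairing folder)")
print(f"rnafold    {fold(seq, engine='rnafold')}   (ViennaRNA MFE adapter)")

# the worked stem-loop example: two stacked stems, a bulge, and a 3' tail
ss = SeqStruct(id="demo", seq=seq, struct="((((...))..))...")
dec = decompose_elements(ss)
print("\nstructural elements (type letters: s stem, h hairpin, i internal/bulge,")
print("m multiloop strand, f/t 5'/3' tails):")
for e in dec.elements:
    print(f"  {e.kind}{len(e.positions)}  positions {e.positions}")

g = build_complete_graph(ss)
print(f"\ncomplete graph: {g.number_of_nodes()} nucleotide nodes, "
      f"{g.number_of_edges()} edges (backbone + base-pair)")

for option in (3, 4, 11):
    h = transform(ss, option)
    nt = sum(1 for n in h.nodes if n[0] == "nt")
    el = sum(1 for n in h.nodes if n[0] == "el")
    print(f"option {option:>2}: {el} element nodes + {nt} nucleotide nodes, "
          f"{h.number_of_edges()} edges")
print("\nOption 3 is the pure element-level (bulge) graph; option 4 adds the")
print("hairpin-loop sequence; option 11 adds the whole nucleotide graph with")
print("paired positions masked to 'P', so stem sequence is invisible.")
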