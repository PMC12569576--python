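"""Assign precursor labels by reverse depth-first search over a pathway DAG.

The nearest-precursor rule stops each backward walk at the first vocabulary
compound, so a diterpenoid built via GGPP is labeled GGPP only and does not
inherit the upstream GPP.
"""

from precursorpred import build_graph, label_table, toy_pathway

graph, vocab, expected = toy_pathway("terpenoid_demo")
table = label_table(graph, ["monoterpenoid", "diterpenoid", "GGPP"], vocab)
print(table)
# The diterpenoid row reads GPP=0, GGPP=1: the walk stopped at GGPP even
# though GPP lies further upstream on the same path.

custom = build_graph([("tryptophan", "tryptamine", "R1"),
                      ("tryptamine", "strictosidine", "R2"),
                      ("secologanin", "strictosidine", "R3")])
from precursorpred import PrecursorVocabulary, precursor_labels

v = PrecursorVocabulary(("tryptophan", "secologanin"))
print("strictosidine precursors:", precursor_labels(custom, "strictosidine", v))
# Both branches of the condensation are found: {tryptophan, secologanin}.
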