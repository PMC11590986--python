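"""Score a tiny hand-checkable corpus with CaseOLAP.

Builds a four-abstract corpus over two disease categories (cardiac
arrhythmias, ARR; cardiomyopathies, CM) and two proteins, then runs the
text-cube / mention-counting / scoring pipeline and prints the mention-count
and score matrices.
"""

from cardiomine.corpus_cube import DocumentRecord
from cardiomine.pipeline import run_pipeline
from cardiomine.vocab import CategoryDefinition, MeshDescriptor, OsDescriptor, ProteinEntity

mesh = {
    "D000001": MeshDescriptor("D000001", "Arrhythmias, Cardiac", ("C14.280.067",)),
    "D000002": MeshDescriptor("D000002", "Cardiomyopathies", ("C14.280.238",)),
}
categories = (
    CategoryDefinition("ARR", "Arrhythmias, cardiac", ("C14.280.067",)),
    CategoryDefinition("CM", "Cardiomyopathies", ("C14.280.238",)),
)
os_vocab = {"D000010": OsDescriptor("D000010", "Glutathione", "MOS", "antioxidants")}
proteins = {
    "P1": ProteinEntity("P1", "ProtOne", ("alpha regulator",)),
    "P2": ProteinEntity("P2", "ProtTwo", ()),
}
docs = [
    DocumentRecord("d1", "t", "ProtOne binds ProtOne", ("D000001",)),
    DocumentRecord("d2", "t", "alpha regulator inhibits ProtTwo", ("D000001", "D000010")),
    DocumentRecord("d3", "t", "ProtTwo and ProtTwo", ("D000002",)),
    DocumentRecord("d4", "t", "nothing relevant here", ("D000002",)),
]

res = run_pipeline(docs, categories, mesh, os_vocab, proteins)

print("Mention counts tf(protein, category):")
print(res.counts.tf, end="\n\n")
print("CaseOLAP scores S = popularity x distinctiveness:")
print(res.scores.score.round(4), end="\n\n")
print(
    "P1 is mentioned only in ARR documents (3 of the 4 ARR-cell mentions),\n"
    "so its distinctiveness there is 1 and S(P1, ARR) = ln(1+3)/ln(1+4) = 0.8614.\n"
    "P2 splits its relative frequency 0.2 / 0.8 between ARR and CM."
)
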