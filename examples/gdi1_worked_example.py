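"""The Gdi1 worked example: a static hub with a few dynamic partners.

Gdi1 is a GDP-dissociation inhibitor with a single interaction interface
and 10 partners (Rab-family GTPases it recycles from membranes). Only 3 of
the partners oscillate in the cell cycle; the rest are constitutive. The
packaged partner list reproduces that picture, and classifying the hub from
those verdicts yields Static / non-competitive.
"""

from hubcycle import (
    build_classification,
    ego_network,
    gdi1_network,
    load_gdi1_partners,
)

network = gdi1_network()
ego = ego_network(network, "GDI1", steps=1)
partners = sorted(set(ego.nodes) - {"GDI1"})
labels = load_gdi1_partners()

print(f"GDI1 partners: {len(partners)}")
for p in partners:
    print(f"  {p:6s} {labels[p]}")

dynamic = sum(labels[p] == "periodic" for p in partners)
print(f"dynamically expressed partners: {dynamic}")

cls = build_classification(
    "GDI1", 1, "aperiodic", [labels[p] for p in partners]
)
print(f"table class: {cls.table_class}; regulatory class: {cls.regulatory_class}")
# A static hub with periodic partners: the cell staggers partner expression
# instead of letting every Rab compete for the single interface at once.
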