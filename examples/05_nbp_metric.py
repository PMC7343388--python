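"""The normalized-basal-position (NBP) contact metric.

A fiber contacting an inner hair cell of length L at distance c from the
basal pole gets NBP = +c/L on the modiolar face and -c/L on the pillar face;
with several contacts the most extreme position counts.
"""

from sgnpos import Contact, ContactGeometry, classify_face, compute_nbp

examples = [
    ("single modiolar contact halfway up", ContactGeometry(
        contacts=[Contact(c=10.0, face="modiolar")], hair_cell_length=20.0)),
    ("single pillar contact near the pole", ContactGeometry(
        contacts=[Contact(c=2.0, face="pillar")], hair_cell_length=20.0)),
    ("branched fiber, extreme contact wins", ContactGeometry(
        contacts=[Contact(c=2.0, face="pillar"), Contact(c=6.0, face="modiolar")],
        hair_cell_length=20.0)),
    ("contact at the basal pole", ContactGeometry(
        contacts=[Contact(c=0.0, face="pillar")], hair_cell_length=20.0)),
]

for label, geom in examples:
    nbp = compute_nbp(geom)
    print(f"{label}: NBP = {nbp:+.2f} -> {classify_face(nbp)} class")

print("\nPositive NBP = modiolar side (high-threshold, low-spontaneous-rate "
      "territory in vivo); negative = pillar side; the zero-NBP basal pole "
      "falls in the modiolar class by the inclusive >= 0 rule.")
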