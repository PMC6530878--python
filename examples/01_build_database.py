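"""Build the canonical 40-condition stimulus battery and inspect it.

Each condition is a central vernier (two vertical bars, the lower one
displaced left or right) optionally surrounded by flanker shapes from one
of 11 categories.  Every category provides the (alone, one flanker, many
flankers) triplet that the crowding benchmark classifies.
"""

from crowdbench import build_database

db = build_database()

print(f"{len(db.entries)} conditions over {len(db.categories())} categories\n")
for cat in db.categories():
    alone, one, many = db.triplet_ids(cat)
    inks = [int((db.condition(c)[0].pixels > 0).sum()) for c in (alone, one, many)]
    print(f"  {cat:18s} triplet={alone}, {one}, {many}   stroke pixels={inks}")

# Stroke pixel counts grow with flanker count; the vernier alone is 80 px
# (two 20x2 bars).  Exporting writes one 8-bit PNG per condition and side
# plus a JSON manifest:
#   db.export_png("stimuli/")
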