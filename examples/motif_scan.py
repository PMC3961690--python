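"""Extended active-site motif extraction, conservation and classification.

Generates a 494-sequence set with residues planted at the extended
active-site positions (aspartate six before the N-terminal motif cysteine;
a distal partner that is glutamine in ~77% of sequences, arginine or lysine
otherwise), extracts the extended site of every -CXXC- motif, tabulates
conservation of the distal-partner slot, and classifies a few exemplary
active-site layouts.
"""

from trxpka import (
    ExtendedSiteRecord,
    MotifSimSpec,
    classify_active_site,
    extract_extended_site,
    find_cxxc,
    gen_motif_sequences,
    tabulate_conservation,
)

spec = MotifSimSpec(
    n_sequences=494,
    seed=11,
    slot_frequencies={
        "beta1_minus6": {"D": 1.0},
        "xx": {"VA": 1.0},
        "alpha1_acidic": {"E": 1.0},
        "partner": {"Q": 380 / 494, "R": 72 / 494, "K": 42 / 494},
    },
)
records, _ = gen_motif_sequences(spec)

sites = []
for rec in records:
    for idx in find_cxxc(rec):
        sites.append(extract_extended_site(rec, idx))

table = tabulate_conservation(sites, "distal_partner")
print(f"distal-partner conservation over {table.total} sequences:")
for res in sorted(table.counts, key=table.counts.get, reverse=True):
    print(f"  {res}: {table.counts[res]:4d}  ({table.percents[res]:.1f}%)")
print("-> at the planted frequencies, glutamine dominates (~77%).")

print("\nclassification of exemplary layouts:")
layouts = [
    ("cDsbD-like", "D", ("Q", 27), "VA"),
    ("E. coli Trx-like", "D", ("K", 25), "GP"),
    ("human Trx / DsbA-like", "E", None, "VH"),
    ("CcmG-like", "A", None, "PY"),
]
for name, beta1, partner, xx in layouts:
    rec = ExtendedSiteRecord(
        sequence_id=name, cys_n_pos=40, xx_residues=xx,
        beta1_minus6=beta1, alpha1_acidic="E", distal_partner=partner,
    )
    cls = classify_active_site(rec)
    print(f"  {name:24s} {cls.rule}: {cls.label}")
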