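"""From ISCN karyotype strings to a filtered copy-number cohort.

Parses numerical karyotypes, applies the cohort exclusion rules
(incomplete karyotypes, markers, rings, adults, no numerical change),
and pools the surviving cases' copy-number class distribution.
"""

from karyolute import filter_cohort, parse_iscn_numerical, pooled_cn_distribution

karyotypes = [
    "49,XX,-1,+2,+3,+4,+4",      # hyperdiploid stem line
    "46,XY",                      # no numerical change -> excluded
    "47,XY,+mar",                 # marker chromosome -> excluded
    "55,XX,+4,+6,+7,+8,+13,+17,+18,+20,+21",
    "70,XXX,+7,dmin",             # dmin implies MYCN amplification (type 2B)
    "46,XX,del(1)(p32),inc",      # incomplete -> excluded
]
records = [parse_iscn_numerical(k, case_id=f"case{i}") for i, k in enumerate(karyotypes, 1)]
kept = filter_cohort(records)

print(f"parsed {len(records)} karyotypes, {len(kept)} kept after exclusion rules\n")
for rec in kept:
    print(f"{rec.case_id}: N={rec.profile.N:3d}  classes {rec.profile.counts}  "
          f"subtype {rec.subtype}")

pooled = pooled_cn_distribution(kept)
print("\npooled copy-number class distribution of the kept cases:")
for k, f in pooled.items():
    name = {1: "monosomy", 2: "disomy", 3: "trisomy", 4: "tetrasomy"}.get(k, f"{k}-somy")
    print(f"  {name:10s} {f:.1%}")
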