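"""Screen four well-characterised peptides with published helicity scores.

The four peptides — the human neuropeptide Y, the bovine-milk cathelicidin
fragment BMAP-28, the human lactoferricin region and the gut-bacteriocin
OR-7 region — span the peptide sources the screen was designed for. Their
published AGADIR helicity scores are fed through the external-score adapter
(strict mode: the table is the sole helicity authority), and the decision
rule plus sliding-window region search does the rest.
"""

from amphiscreen import ExternalScores, PeptideRecord, ScreenConfig, screen_batch

records = [
    PeptideRecord("NPY", "YPSKPDNPGEDAPAEDMARYYSALRHYINLITRQRY",
                  source="human neuropeptide"),
    PeptideRecord("BMAP28", "GGLRSLGRKILRAWKKYG", source="food-derived AMP"),
    PeptideRecord("LfcinH", "GRRRRSVQWCAVSQPEATKCFQWQRNMRKVRGPPVSCIKRDSPIQCIQ",
                  source="human AMP"),
    PeptideRecord("OR7_region", "MGRLQDILLGWATGAFGKTF", source="gut bacteriocin"),
]

# Published percent-helicity scores; region candidates are matched by sequence.
scores = ExternalScores({
    "BMAP28": 1.6,
    "OR7_region": 1.0,
    "DMARYYSALRHYINLITRQRY": 12.0,              # NPY region 16-36
    "QWCAVSQPEATKCFQWQRNMRKVRGPPVSCIKRDSPIQ": 1.0,  # LfcinH region
})

results = screen_batch(records, ScreenConfig(), scores)

print(f"{'id':10s} {'decision':16s} {'uH':>5s} {'NCPR':>6s} region")
for res in results:
    p = res.full_length
    region = (f"{res.region.start}-{res.region.sequence}-{res.region.end}"
              if res.region else "-")
    print(f"{res.record_id:10s} {res.decision:16s} {p.uh:5.2f} {p.ncpr:+6.2f} {region}")

print(
    "\npositive_full: the whole peptide satisfies all four criteria "
    "(helicity >= 1, uH >= 0.2,\n>= 1 positive residue per 18, 18-54 residues); "
    "positive_region: only the printed internal\nstretch does. uH and NCPR "
    "are the full-length amphipathic moment and net charge per residue."
)
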