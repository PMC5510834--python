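"""The candidate-prioritization cascade on simulated strain-specific variants.

Per-transcript consequence annotations are collapsed to one term per variant
by severity precedence; non-synonymous (protein-altering) variants are kept;
the five-criterion high-confidence filter (depth >= 10, QUAL >= 30, MQ >= 40,
GQ >= 20, >= 80% alt reads) is applied; and the survivors are screened
against two external strain panels for privacy.  The cascade report shows
the attrition at each tier.
"""

from strainscreen import (
    cascade_report,
    collapse_consequences,
    high_confidence_filter,
    privacy_screen,
    select_nonsynonymous,
    strain_specific_variants,
)
from strainscreen.simulate import SimConfig, simulate_panels, simulate_strains

cfg = SimConfig(seed=42)
sim = simulate_strains(cfg)
set_a, _ = strain_specific_variants(sim.callset_a, sim.callset_b)

collapsed = collapse_consequences(sim.consequences)
nonsyn = select_nonsynonymous(collapsed)
specific = {c.locus for c in set_a.variants}
specific_nonsyn = specific & nonsyn
hc = {c.locus for c in high_confidence_filter(
    [c for c in set_a.variants if c.locus in specific_nonsyn])}

panel28, panel40 = simulate_panels(cfg, sim.truth)
private, seen = privacy_screen(hc, [panel28, panel40])

report = cascade_report([
    ("strain-A specific", specific),
    ("non-synonymous", specific_nonsyn),
    ("high-confidence", hc),
    ("private (absent from both panels)", set(private)),
])
print(report.to_string(index=False))
print("\nEach tier is a subset of the one above; the percentage is relative")
print("to the first tier. 'Private' variants are additionally absent from")
print("the 28- and 40-strain external panels and are the candidates carried")
print("into the F2 co-segregation screen.")
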