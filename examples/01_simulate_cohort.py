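"""Simulate a synthetic cancer cohort with known mutational-process archetypes.

Builds a 2 Mb reference with planted homopolymer tracts and motif occurrences,
draws 40 samples from four archetypes (UV-like, MSI-like, tobacco-like,
neutral), writes one VCF per sample plus a manifest, and prints the drawn
loads.  The printed medians show the archetype contrasts the downstream
analysis is meant to recover: UV-like and tobacco-like are SSM-heavy while
MSI-like carries an order of magnitude more indels.
"""

import tempfile

from recurmut.synthetic import (
    ReferenceSpec,
    default_archetypes,
    generate_cohort,
    generate_reference,
)

spec = ReferenceSpec.default(contig_length=2_000_000)
spec.motif_occurrences = {"TTTCCT": 600}
spec.homopolymer_tracts = {(b, l): 50 for b in "ACGT" for l in (8, 9, 10)}
genome, element_map = generate_reference(spec, seed=1)
print(f"reference: {genome.length('ctg1'):,} bp, "
      f"{len(element_map):,} planted elements")

cohort = generate_cohort(
    [(a, 10) for a in default_archetypes()], genome, element_map, seed=2
)
print(f"cohort: {cohort.truth.sample_id.nunique()} samples, "
      f"{len(cohort.calls):,} calls")

loads = cohort.loads.set_index("sample_id")
loads["archetype"] = cohort.truth_labels
print("\nmedian drawn loads per archetype:")
print(loads.groupby("archetype").median().round(0))

with tempfile.TemporaryDirectory() as out:
    manifest = cohort.write_vcfs(out, genome)
    print(f"\nwrote {len(manifest)} VCFs + manifest.tsv to {out}")
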