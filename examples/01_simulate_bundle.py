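"""Generate a synthetic hair-follicle study and inspect its planted truth.

The bundle holds a toy genome, a protein-coding reference annotation,
assembled transcripts with lncRNAs planted in all six genomic contexts
plus reject-class transcripts, a known-lncRNA database, a 6-stage x
3-replicate FPKM table and a term annotation.  Everything is
deterministic for a fixed seed.
"""

from folliscan import GeneratorConfig, generate_bundle, write_fixture_bundle

bundle = generate_bundle(GeneratorConfig(seed=1))

print(f"genome: {len(bundle.genome['chr1']):,} bp")
print(f"reference genes: {len(bundle.reference)}  assembled transcripts: {len(bundle.assembled)}")
print("\nplanted roles:")
print(bundle.truth.planted_role.value_counts().to_string())
print("\nplanted contexts (lncRNAs only):")
lnc = bundle.truth[bundle.truth.planted_role.isin(["lncRNA", "known_lncRNA"])]
print(lnc.planted_context.value_counts().to_string())

manifest = write_fixture_bundle(bundle, "scratch/example_bundle")
print(f"\nbundle written; config hash {manifest['config_hash']}")
# The role/context tallies above are the generator's plan: each of the six
# genomic-context categories receives five lncRNAs, and each identification
# filter gets four transcripts planted to fail exactly there.
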