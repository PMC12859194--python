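"""Call back-splice junctions from segment alignments and annotate them.

A back-splice shows up as two consecutive segments of one read whose
genomic order is inverted relative to read order. Called junctions are
annotated to host genes by exact exon-boundary match, and the 200-nt
junction sequence (100 nt each side of the back-splice) is assembled for
each circle.
"""

from cernaforge import circdetect
from cernaforge.simulate import SimConfig, simulate_dataset

ds = simulate_dataset(SimConfig(seed=42, n_genes=80, n_circ=15, n_mirnas=12,
                                depth=3e4, circ_reads_mean=120.0,
                                linear_reads_mean=6.0))

junctions = circdetect.call_backsplice(ds.segments)
records = circdetect.annotate(junctions, ds.models)

print(f"called {len(junctions)} junctions "
      f"({(records.status == 'annotated').sum()} annotated to a host gene)")
row = records.iloc[0]
print(f"example: {row.circ_id} -> host {row.host_gene}, "
      f"exons {row.exon_first}..{row.exon_last}, "
      f"spliced length {row.spliced_length} nt")

spliced = circdetect.circ_spliced_sequence(ds.genome, row)
jseq = circdetect.junction_sequence(spliced, flank=100)
print(f"junction sequence: {len(jseq)} nt "
      f"({jseq[:12]}...{jseq[-12:]}), centered on the back-splice point;")
print("this is the amplicon a divergent qPCR primer pair or a pulldown "
      "probe would be designed against.")

truth = {(r.chrom, r.start, r.end, r.strand) for r in ds.truth_junctions().itertuples()}
called = {(r.chrom, r.start, r.end, r.strand) for r in junctions.itertuples()}
print(f"false calls vs simulator truth: {len(called - truth)} "
      f"(recall {len(called & truth)}/{len(truth)})")
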