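"""Build a splice graph and LSV catalog for a cassette-exon gene.

A cassette exon produces exactly two local splicing variations (LSVs): a
single-source split from the upstream exon (include vs skip junction) and a
single-target split into the downstream exon.
"""

from lsvtools import GeneModel, Transcript, build, classify_lsv

gene = GeneModel(
    gene_id="demo",
    chrom="chr1",
    strand="+",
    transcripts=[
        Transcript("demo.t1", [(100, 200), (500, 600), (900, 1000)]),  # inclusion
        Transcript("demo.t2", [(100, 200), (900, 1000)]),              # skipping
    ],
)

graphs, lsvs = build([gene])
g = graphs["demo"]

print(f"exons: {[e.interval for e in g.exons]}")
print(f"junctions: {[(j.key.donor_end, j.key.acceptor_start) for j in g.junctions]}")
for lsv in lsvs:
    print(f"{lsv.lsv_id}  type={classify_lsv(lsv, g)}  "
          f"junctions={lsv.n_junctions}  complex={lsv.is_complex}")

# Expected: 3 exons, 3 junctions (two inclusion, one skip), and — before the
# existence filter — two binary LSVs sharing the skip junction.  `build`
# applies the default existence filter, so with zero read evidence the list
# is empty; pass simulated or real counts to retain LSVs.
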