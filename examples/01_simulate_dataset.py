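"""Generate the synthetic 3-age-group study and inspect its planted truth.

The generator emulates a 3-group x 3-replicate RNA-seq design: an annotated
genome, mRNA/lncRNA/circRNA/miRNA counts, back-splice candidates, miRNA
target tables, and coding-potential flags — with ceRNA triplets, DE features
and positional classes planted and recorded.
"""

from cerna_forge import GeneratorConfig, generate_dataset

ds = generate_dataset(GeneratorConfig(), seed=1)

print("samples:", ", ".join(ds.design.sample_ids))
print("genes + lncRNAs in count matrix:", ds.gene_expr.values.shape)
print("circRNA candidates:", len(ds.circ_candidates))
print("planted ceRNA triplets (anchor miRNA, sponge, mRNA):")
for t in ds.truth.cerna_triplets:
    print("  ", t)
print("planted DE features:", ds.truth.de_features)
# Every planted id exists in the generated tables, so downstream stages can
# be scored against this truth.
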