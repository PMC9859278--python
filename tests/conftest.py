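import pytest

from cerna_forge.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def dataset():
    """Reference synthetic study (default conditions, seed 1)."""
    return generate_dataset(GeneratorConfig(), seed=1)


@pytest.fixture(scope="session")
def tiny_gtf(tmp_path_factory):
    """Two-gene annotation written as GTF: one gene per strand, 3 exons each."""
    text = "\n".join([
        'chr1\tx\tgene\t1001\t10000\t.\t+\t.\tgene_id "gA"; gene_biotype "protein_coding";',
        'chr1\tx\ttranscript\t1001\t10000\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t1";',
        'chr1\tx\texon\t1001\t2000\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t1";',
        'chr1\tx\texon\t5001\t6000\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t1";',
        'chr1\tx\texon\t9001\t10000\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t1";',
        'chr1\tx\tgene\t50001\t59000\t.\t-\t.\tgene_id "gB"; gene_biotype "protein_coding";',
        'chr1\tx\ttranscript\t50001\t59000\t.\t-\t.\tgene_id "gB"; transcript_id "gB.t1";',
        'chr1\tx\texon\t50001\t51000\t.\t-\t.\tgene_id "gB"; transcript_id "gB.t1";',
        'chr1\tx\texon\t58001\t59000\t.\t-\t.\tgene_id "gB"; transcript_id "gB.t1";',
    ]) + "\n"
    p = tmp_path_factory.mktemp("ann") / "tiny.gtf"
    p.write_text(text)
    return p
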