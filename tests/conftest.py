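import numpy as np
import pytest

from biisq import GeneModel, Hyperparameters, Isoform


@pytest.fixture
def brca2_head() -> GeneModel:
    """First two exons of the BRCA2 worked example, half-open coordinates."""
    return GeneModel("BRCA2", ((1, 67), (2617, 2865)), strand="+", chrom="chr13")


@pytest.fixture
def gene4() -> GeneModel:
    """Four 150 bp exons with 100 bp introns."""
    return GeneModel("G4", ((0, 150), (250, 400), (500, 650), (750, 900)))


@pytest.fixture
def gene6() -> GeneModel:
    return GeneModel("G6", tuple((i * 250, i * 250 + 150) for i in range(6)))


@pytest.fixture
def gene3() -> GeneModel:
    """Three 30 bp exons, abutting-free layout for small walk tests."""
    return GeneModel("G3", ((0, 30), (100, 130), (200, 230)))


@pytest.fixture
def hyp() -> Hyperparameters:
    return Hyperparameters()


@pytest.fixture
def disjoint_pair() -> list[Isoform]:
    return [Isoform((1, 1, 0, 0)), Isoform((0, 0, 1, 1))]


def write_small_gtf(path, gene_id="GENE1", chrom="chr1", strand="+"):
    """Two-transcript GTF: a 2-exon 'basic' transcript and a 3-exon one."""
    lines = []

    def feat(kind, start, end, tid, tags=""):
        attrs = f'gene_id "{gene_id}"; transcript_id "{tid}";{tags}'
        return f"{chrom}\ttest\t{kind}\t{start}\t{end}\t.\t{strand}\t.\t{attrs}"

    lines.append(feat("transcript", 1, 900, "T1", ' tag "basic";'))
    for s, e in ((1, 150), (251, 400)):
        lines.append(feat("exon", s, e, "T1", ' tag "basic";'))
    lines.append(feat("transcript", 1, 900, "T2", ' tag "basic";'))
    for s, e in ((1, 150), (251, 400), (501, 650)):
        lines.append(feat("exon", s, e, "T2", ' tag "basic";'))
    path.write_text("\n".join(lines) + "\n")
    return path
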