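import numpy as np
import pandas as pd
import pytest

from popadapt.core import GenotypeMatrix
from popadapt.simulate import SimConfig, simulate_dataset, write_fixture


@pytest.fixture(scope="session")
def small_bundle():
    """Default-style nested cohort, scaled for unit tests."""
    cfg = SimConfig(seed=11, n_neutral_loci=3000, n_adaptive_loci=30)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """An on-disk fixture bundle (VCF + tables + GFF + truth)."""
    cfg = SimConfig(seed=23, n_neutral_loci=1200, n_adaptive_loci=12)
    bundle = simulate_dataset(cfg)
    out = tmp_path_factory.mktemp("fixture")
    manifest = write_fixture(bundle, out, overwrite=True)
    return bundle, manifest


def make_matrix(dosage, positions=None, chrom="chr1", samples=None):
    """Small GenotypeMatrix from a (samples x loci) array."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, L = dosage.shape
    positions = positions if positions is not None else np.arange(1, L + 1) * 10
    samples = samples or [f"S{i + 1}" for i in range(n)]
    loci = pd.DataFrame({"chrom": chrom, "pos": positions,
                         "ref": "A", "alt": "T", "id": None})
    return GenotypeMatrix(samples, loci, dosage)


@pytest.fixture
def toy_matrix():
    return make_matrix


def write_toy_vcf(path, records, samples=("S1", "S2", "S3", "S4")):
    """Write a minimal VCF from (chrom,pos,ref,alt,qual,gt_strings) tuples."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="DP">\n')
        fh.write("##contig=<ID=chr1>\n##contig=<ID=chr2>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for chrom, pos, ref, alt, qual, gts in records:
            fh.write("\t".join([chrom, str(pos), ".", ref, alt, str(qual),
                                "PASS", ".", "GT:DP", *gts]) + "\n")
    return path
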