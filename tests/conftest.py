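import numpy as np
import pytest

from seagea.simgen import SimConfig, generate_fixture


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """A small but complete synthetic seascape written to disk."""
    outdir = tmp_path_factory.mktemp("fixture")
    cfg = SimConfig(n_neutral=300, n_adaptive=15, per_site_n=10, seed=9)
    return generate_fixture(cfg, outdir=outdir)


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=chr1>\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_vcf_text(path, sample_ids, records):
    """records: list of (chrom, pos, id, ref, alt, [gt strings])."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids) + "\n"
        )
        for chrom, pos, vid, ref, alt, gts in records:
            fh.write(
                f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )
    return path


@pytest.fixture
def vcf_writer(tmp_path):
    def _write(sample_ids, records, name="test.vcf"):
        return str(write_vcf_text(tmp_path / name, sample_ids, records))

    return _write


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
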