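import numpy as np
import pytest

from epiforest import GenotypeMatrix, PhenotypeVector, LabelSimSpec, gen_features, gen_label


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


@pytest.fixture
def make_vcf(tmp_path):
    """Write a small VCF from (samples, records) and return its path."""

    def _make(samples, records, name="test.vcf"):
        path = tmp_path / name
        lines = [VCF_HEADER.rstrip("\n")]
        lines.append(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
        )
        for chrom, pos, ref, alt, gts in records:
            lines.append(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\tGT\t" + "\t".join(gts)
            )
        path.write_text("\n".join(lines) + "\n")
        return path

    return _make


@pytest.fixture
def tiny_matrix():
    """Deterministic 8-sample x 5-variant matrix with all three genotypes."""
    rng = np.random.default_rng(42)
    values = rng.integers(0, 3, size=(8, 5))
    return GenotypeMatrix(
        values,
        tuple(f"v{j}" for j in range(5)),
        tuple(f"s{i}" for i in range(8)),
    )


@pytest.fixture
def planted_dataset():
    """Additive phenotype with a clean 3-variant signal (no noise variants)."""
    matrix = gen_features(300, 60, seed=7)
    spec = LabelSimSpec(k_causal=3, gm=0.0, gs=0.0, gvf=0.0, seed=8)
    phenotype, truth = gen_label(matrix, spec)
    return matrix, phenotype, truth
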