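import numpy as np
import pytest
from hypothesis import settings

import exoncnv as x

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def thresholds():
    return x.Thresholds()


def make_bin(
    chromosome="chr1",
    start=1000,
    end=1150,
    gene="GENA",
    depth=200.0,
    log2=0.0,
    weight=1.0,
    exon_index=1,
    p_value=None,
    het_del_freq=None,
    hom_del_freq=None,
    dup_freq=None,
    thresholds=x.Thresholds(),
):
    """Construct a consistent AnnotatedBin for tests."""
    return x.AnnotatedBin(
        chromosome=chromosome,
        start=start,
        end=end,
        gene=gene,
        depth=depth,
        log2=log2,
        weight=weight,
        p_value=p_value,
        exon_index=exon_index,
        call=x.classify_log2(log2, thresholds),
        cn=x.log2_to_cn(log2),
        het_del_freq=het_del_freq,
        hom_del_freq=hom_del_freq,
        dup_freq=dup_freq,
        highlight=log2 < thresholds.grid_highlight_log2,
    )


def make_ref_stats(gene="GENA", chromosome="chr1", exon_index=1, mean_log2=0.0,
                   sd_log2=0.25, n_samples=10, het_del_freq=0.0, hom_del_freq=0.0,
                   dup_freq=0.0, mean_depth=200.0, sd_depth=20.0):
    """A reference row with coherent ordering of its summary statistics."""
    return x.ExonReferenceStats(
        gene=gene, chromosome=chromosome, exon_index=exon_index,
        n_samples=n_samples, het_del_freq=het_del_freq,
        hom_del_freq=hom_del_freq, dup_freq=dup_freq,
        mean_log2=mean_log2, median_log2=mean_log2, sd_log2=sd_log2,
        q1_log2=mean_log2 - sd_log2, q3_log2=mean_log2 + sd_log2,
        min_log2=mean_log2 - 3 * sd_log2, max_log2=mean_log2 + 3 * sd_log2,
        mean_depth=mean_depth, median_depth=mean_depth, sd_depth=sd_depth,
        q1_depth=mean_depth - sd_depth, q3_depth=mean_depth + sd_depth,
        min_depth=max(0.0, mean_depth - 3 * sd_depth), max_depth=mean_depth + 3 * sd_depth,
    )


@pytest.fixture
def demo_cohort():
    spec = x.demo_spec(seed=11)
    return spec, x.synth_cohort(spec)


def random_annotated_fixture(rng: np.random.Generator, n_genes=2, max_exons=12):
    """Random exon-indexed AnnotatedBins over a couple of genes."""
    bins = []
    for g in range(n_genes):
        gene = f"G{g}"
        n_exons = int(rng.integers(3, max_exons + 1))
        for e in range(1, n_exons + 1):
            log2 = float(rng.normal(0, 0.8))
            bins.append(
                make_bin(gene=gene, chromosome="chr1", start=1000 * e,
                         end=1000 * e + 150, exon_index=e, log2=log2,
                         depth=float(rng.uniform(10, 400)))
            )
    return bins
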