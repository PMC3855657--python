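import numpy as np
import pandas as pd
import pytest

from tivscan.genemodel import GeneModel, GenomicInterval, Isoform
from tivscan.synthetic import SimulationSpec, simulate_arrays, simulate_gene_models


def make_isoform(iso_id, gene_id, exons, chrom="chr1", strand="+"):
    return Isoform(
        iso_id,
        gene_id,
        tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
    )


def make_gene(gene_id, exon_lists, chrom="chr1", strand="+"):
    return GeneModel(
        gene_id,
        tuple(
            make_isoform(f"{gene_id}.{k+1}", gene_id, exons, chrom, strand)
            for k, exons in enumerate(exon_lists)
        ),
    )


@pytest.fixture(scope="session")
def promoter_switch_gene():
    """Long isoform with two unique upstream exons, short isoform with an
    internal alternative first exon, shared 3' exons."""
    shared = [(2000, 2150), (2500, 2650), (3000, 3200)]
    long_iso = [(100, 220), (500, 620)] + shared
    short_iso = [(1200, 1320)] + shared
    return make_gene("PSWG1", [long_iso, short_iso])


@pytest.fixture(scope="session")
def small_sim():
    """Small simulated array experiment with injected DE and TIV."""
    spec = SimulationSpec(seed=11, n_genes=120, tiv_fraction=0.2, de_fraction=0.1)
    models, ps_table, matrix, sheet, truth = simulate_arrays(spec)
    return spec, models, ps_table, matrix, sheet, truth


@pytest.fixture(scope="session")
def random_models():
    """~500 random models covering every event class plus plain genes."""
    models = {}
    truths = []
    for seed in range(4):
        spec = SimulationSpec(seed=seed, n_genes=125, tiv_fraction=0.8)
        m, _ps, truth = simulate_gene_models(spec)
        for gid, model in m.items():
            models[f"s{seed}_{gid}"] = model
        t = truth.genes.copy()
        t.index = [f"s{seed}_{g}" for g in t.index]
        truths.append(t)
    return models, pd.concat(truths)
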