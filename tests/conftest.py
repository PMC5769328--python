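import numpy as np
import pytest

from hlacall import (
    PipelineConfig,
    SimulationSpec,
    deduplicate,
    make_toy_database,
    simulate_reads,
)

# The standard study conditions: three typed genes of 12 highly homologous
# alleles (~800 bp CDS, 4 substitutions from the gene ancestor) plus one
# 95%-identical pseudogene companion of gene A, heterozygous diploid truth,
# error-free 100 bp single-end reads at first-base depth 30 with 20% PCR
# duplicates.
STANDARD_DB = dict(
    n_genes=3,
    alleles_per_gene=12,
    cds_len=800,
    divergence=4,
    paralog_pairs=[("A", "H")],
    seed=7,
)
STANDARD_SIM = dict(depth=30.0, read_len=100, dup_rate=0.2, error_rate=0.0)


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def std_db():
    return make_toy_database(**STANDARD_DB)


def pick_truth(db, seed, homozygous=False):
    """Deterministic truth genotype over every gene of the database."""
    rng = np.random.default_rng(seed)
    truth = {}
    for gene in db.genes():
        names = [r.name for r in db.alleles_by_gene[gene]]
        if homozygous:
            a = str(rng.choice(names))
            truth[gene] = (a, a)
        else:
            pair = rng.choice(names, size=2, replace=False)
            truth[gene] = (str(pair[0]), str(pair[1]))
    return truth


def simulate_standard(db, seed, homozygous=False, **overrides):
    """One standard simulated library plus its deduplicated read set."""
    params = {**STANDARD_SIM, **overrides}
    truth = pick_truth(db, seed, homozygous=homozygous)
    sim = simulate_reads(db, SimulationSpec(truth=truth, seed=seed, **params))
    return sim, deduplicate(sim.id_seq_pairs())


@pytest.fixture(scope="session")
def std_run(std_db, cfg):
    """One full standard simulation + pipeline run shared across tests."""
    from hlacall import call_genotypes

    sim, rs = simulate_standard(std_db, seed=0)
    report, diag = call_genotypes(std_db, rs, cfg)
    return sim, rs, report, diag
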