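import pytest

from ilpkit import genome_io, primer_design, synthetic_data


@pytest.fixture(scope="session")
def sim_genome():
    """A 2-chromosome, 20-gene annotated toy genome with known introns."""
    cfg = synthetic_data.SimGenomeConfig(seed=11, n_chromosomes=2,
                                         genes_per_chromosome=10)
    records, models, truth = synthetic_data.simulate_annotated_genome(cfg)
    return records, models, truth


@pytest.fixture(scope="session")
def sim_introns(sim_genome):
    records, models, _ = sim_genome
    return genome_io.extract_introns(records, models, 80, 300)


@pytest.fixture(scope="session")
def sim_pairs(sim_genome, sim_introns):
    return primer_design.design_primers(sim_introns, source_genome="base")
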