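import numpy as np
import pytest

from fulquant.simulate import SimConfig, make_toy_reference, simulate_reads


@pytest.fixture(scope="session")
def perfect_dataset(tmp_path_factory):
    """Small error-free simulated dataset with files on disk."""
    out = tmp_path_factory.mktemp("perfect")
    config = SimConfig.perfect(seed=3, n_genes=5, total_molecules=600,
                               min_molecules_per_isoform=5)
    rng = np.random.default_rng(config.seed)
    truth = make_toy_reference(config, rng)
    truth.write_fasta(out / "genome.fa")
    truth.write_gtf(out / "truth.gtf")
    truth.write_counts(out / "truth_counts.tsv")
    reads = simulate_reads(truth, config, rng,
                           fastq_path=out / "reads.fastq",
                           sam_path=out / "reads.sam",
                           provenance_path=out / "provenance.tsv")
    return {"dir": out, "config": config, "truth": truth, "reads": reads}
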