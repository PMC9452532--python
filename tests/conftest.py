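import numpy as np
import pytest

from esccmut import simulate as sim


@pytest.fixture(scope="session")
def toy_cohort():
    """Small two-dataset cohort (one WGS, one masked WES) with planted panel."""
    models = [sim.GeneModel(f"G{i}", 1200 + 250 * i, 0.04 + 0.02 * i, 0.02)
              for i in range(6)]
    cfg = sim.SimulationConfig(
        dataset_sizes=[80, 60],
        gene_models=models,
        platform_masks=[0.0, 0.15],
        panel_truth={"G1": float(np.log(2.0))},
        signature_truth=sim.random_signatures(3, seed=4),
        exposure_truth=np.array([[0.7, 0.2, 0.1], [0.1, 0.6, 0.3]]),
        mutations_per_genome=60,
        seed=42,
    )
    return sim.simulate_cohort(cfg)


@pytest.fixture()
def maf_file(tmp_path, toy_cohort):
    path = tmp_path / "toy.maf.tsv"
    toy_cohort.records.to_csv(path, sep="\t", index=False)
    return path
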