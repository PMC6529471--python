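import pytest

from gvppanel import MissenseSNP, SimulationConfig, simulate_scenario


@pytest.fixture
def krt32_snp():
    """The KRT32 T/M locus on a scaffold built around its printed GVPs.

    Genotype frequencies are fixture numbers (the real population values are
    not part of the catalog contract).
    """
    return MissenseSNP(
        snp_id="rs2071563",
        gene="KRT32",
        protein_accession="P_K32",
        residue_position=10,
        major_aa="T",
        minor_aa="M",
        genotype_freqs=(0.49, 0.42, 0.09),
    )


@pytest.fixture
def krt32_proteome():
    # digest at 0 missed cleavages: MAR | LEGEINTYR | AK
    return {"P_K32": "MARLEGEINTYRAK"}


@pytest.fixture(scope="session")
def noiseless_scenario():
    """Full default design with perfect detection (s = 1, fp = 0)."""
    config = SimulationConfig(seed=20260923, sensitivity=1.0, false_positive_rate=0.0)
    return simulate_scenario(config)


@pytest.fixture(scope="session")
def noisy_scenario():
    """Default design with the default dropout level."""
    return simulate_scenario(SimulationConfig(seed=42))
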