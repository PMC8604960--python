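import numpy as np
import pytest

from dibs.core import DockingRun, EnsembleDockingTable, ProteinDefinition


@pytest.fixture
def protein10() -> ProteinDefinition:
    return ProteinDefinition("ACDEFGHIKL", name="toy10")


@pytest.fixture
def protein93() -> ProteinDefinition:
    return ProteinDefinition("A" * 93, name="synthetic93")


def make_table(protein, contacts_per_run, kds, label="idp", replicate=1, energies=None):
    """Small docking table from explicit contact sets and Kd values (molar)."""
    from dibs.core import delta_g_from_kd

    runs = []
    for i, (contact, kd) in enumerate(zip(contacts_per_run, kds)):
        energy = energies[i] if energies is not None else delta_g_from_kd(kd)
        runs.append(
            DockingRun(
                run_id=i + 1,
                conformer_id=i + 1,
                binding_energy=energy,
                dissociation_constant=kd,
                contact_residues=frozenset(contact),
            )
        )
    return EnsembleDockingTable(runs, label, replicate, protein)


@pytest.fixture
def table_builder():
    return make_table


@pytest.fixture
def random_tables(protein10):
    """Factory for random docking tables with given seed."""

    def build(seed, n_runs=50, label="idp", replicate=1):
        rng = np.random.default_rng(seed)
        contacts = [
            set(rng.choice(protein10.residue_numbers, size=rng.integers(0, 6), replace=False))
            for _ in range(n_runs)
        ]
        kds = 10.0 ** rng.normal(-6, 0.5, n_runs)
        return make_table(protein10, contacts, kds, label=label, replicate=replicate)

    return build
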