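"""Shared fixtures: tiny hand-built assemblies and session-scoped forged
genomes (all inputs are generated programmatically at test time)."""

import pytest

from inil import synthetic_forge as sf
from inil.core_io import GenomeAssembly, ScaffoldRecord


def make_assembly(**seqs: str) -> GenomeAssembly:
    return GenomeAssembly([ScaffoldRecord(k, v) for k, v in seqs.items()])


@pytest.fixture(scope="session")
def forged_default():
    """The standard forged study: 5-Mb genome, 50 intact + 5 rearranged
    elements, telomeres, centromeres, rDNA, markers, BAC pairs."""
    return sf.forge_genome(sf.ForgeConfig(seed=11))


@pytest.fixture(scope="session")
def forged_chimeras():
    """Chimera suite: 10 gap-junction chimeras, 3 gap-free contig
    chimeras, 20 clean marker-bearing chromosomes."""
    cfg = sf.ForgeConfig(
        seed=7, n_chromosomes=20,
        tpn=sf.TpnForgeConfig(n_intact=0, n_rearranged=0),
        chimera=sf.ChimeraForgeConfig(n_events=10, n_contig_events=3),
        bac=sf.BacForgeConfig(n_pairs=0))
    return sf.forge_genome(cfg)
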