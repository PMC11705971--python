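"""Shared fixtures: small forged datasets reused across test modules."""

import numpy as np
import pytest

from proviscope import synthgenome as sg


@pytest.fixture(scope="session")
def forged_replicon():
    """One fully ground-truthed replicon: host + single implanted provirus.

    Sized well above the 10-kbp span floor but small enough that boundary
    scans stay fast.
    """
    config = sg.ForgeConfig(
        rng_seed=11,
        host_length=25_000,
        provirus_length_range=(10_500, 14_000),
        dr_length=30,
        dr_mismatches=0,
        trna_at_boundary=True,
        integrase_end="left",
    )
    rng = np.random.default_rng(np.random.SeedSequence(config.rng_seed))
    replicon, truths, genes = sg.forge_replicon(config, "SYNREP", rng)
    return config, replicon, truths[0], genes


@pytest.fixture(scope="session")
def nested_crispr_locus():
    """A small nested CRISPR locus: two arrays inside one cas cluster."""
    specs = [
        sg.CrisprArraySpec(n_spacers=6, repeat_length=30, with_cas_cluster=True),
        sg.CrisprArraySpec(n_spacers=4, repeat_length=30, with_cas_cluster=True),
    ]
    rng = np.random.default_rng(42)
    seq, truth = sg.forge_crispr_locus(specs, rng)
    return seq, truth
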