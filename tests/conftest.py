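"""Shared fixtures: simulated datasets reused across the suite.

All fixed-seed simulations use seed 1 (the suite-wide convention).
"""

from __future__ import annotations

import numpy as np
import pytest

from annodiff import pipeline, synthetic

RECOVERY_SEED = 1


def clean_config(**overrides) -> synthetic.SimConfig:
    """Study conditions with every artifact class switched off."""
    base = dict(
        seed=RECOVERY_SEED,
        n_false_genes=0,
        n_splits_a=0,
        n_splits_b=0,
        n_inparalog_duplications=0,
        n_intron_gains_a=0,
        n_intron_gains_b=0,
        n_intron_losses_a=0,
        n_intron_losses_b=0,
        n_contaminant_scaffolds=0,
    )
    base.update(overrides)
    return synthetic.SimConfig(**base)


def truth_paired_estimates(dataset: synthetic.SimulatedDataset) -> list[pipeline.PairEstimate]:
    """Masked Ka/Ks per gene, pairing A and B genes by shared ancestry id."""
    cfg = pipeline.AuditConfig()
    pa, ca = pipeline.coding_sequences(dataset.genome_a)
    pb, cb = pipeline.coding_sequences(dataset.genome_b)
    return [
        pipeline.masked_kaks(pa[g], pb[g], ca[g], cb[g], cfg, g, g)
        for g in sorted(set(pa) & set(pb))
    ]


@pytest.fixture(scope="session")
def default_dataset() -> synthetic.SimulatedDataset:
    """Full study conditions: 200 genes plus the whole artifact battery."""
    return synthetic.simulate(synthetic.SimConfig(seed=RECOVERY_SEED))


@pytest.fixture(scope="session")
def default_audit(default_dataset):
    ds = default_dataset
    return pipeline.run_audit(
        ds.genome_a,
        ds.genome_b,
        ds.outgroup,
        expression_a=ds.expression["A"],
        expression_b=ds.expression["B"],
    )


@pytest.fixture(scope="session")
def ks_recovery():
    """Mean estimated Ks and median omega at three simulated Ks levels."""
    out = {}
    for ks_star in (0.01, 0.05, 0.2):
        ds = synthetic.simulate(
            clean_config(n_genes=200, branch_silent_divergence=ks_star / 2)
        )
        ests = truth_paired_estimates(ds)
        ks = [p.estimate.Ks for p in ests if p.estimate.Ks is not None]
        om = [p.estimate.omega for p in ests if p.estimate.omega is not None]
        out[ks_star] = (float(np.mean(ks)), float(np.median(om)))
    return out


@pytest.fixture(scope="session")
def relrate_recovery():
    """Relative-rate contrast on a 2x asymmetric pair (B branch doubled)."""
    from annodiff import divergence as dv

    cfg = pipeline.AuditConfig()
    ds = synthetic.simulate(
        clean_config(
            n_genes=200,
            branch_silent_divergence=0.025,
            branch_silent_divergence_b=0.05,
        )
    )
    pa, ca = pipeline.coding_sequences(ds.genome_a)
    pb, cb = pipeline.coding_sequences(ds.genome_b)
    po, co = pipeline.coding_sequences(ds.outgroup)
    per_gene = []
    for g in sorted(pa):
        ea = pipeline.masked_kaks(pa[g], po[g], ca[g], co[g], cfg).estimate
        eb = pipeline.masked_kaks(pb[g], po[g], cb[g], co[g], cfg).estimate
        per_gene.append((g, ea, eb))
    return dv.relative_rate(per_gene)


@pytest.fixture(scope="session")
def small_clean_genome():
    """A modest artifact-free genome for structural unit tests."""
    return synthetic.make_ancestor(clean_config(n_genes=25, n_scaffolds=2))
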