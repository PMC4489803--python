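"""Shared fixtures: hand-built toy call sets and one simulated pair."""

import numpy as np
import pandas as pd
import pytest

from varconcord.io import CallSet, VariantCall
from varconcord.simulate import SimulationConfig, simulate_replicate_set


def make_variant(pos, ref="A", alt="G", genotype=None, chrom="chr1", **factors):
    return VariantCall(
        chrom=chrom, pos=pos, ref=ref,
        genotype=genotype or (ref, alt), variant_allele=alt, **factors,
    )


def make_callset(positions, sample_id="s", replicate_id="r",
                 genotypes=None, chrom="chr1", **factors):
    """Call set with variants A>G at the given positions; ``genotypes``
    optionally overrides the het (A,G) default per position."""
    cs = CallSet(sample_id=sample_id, replicate_id=replicate_id)
    for i, pos in enumerate(positions):
        gt = None if genotypes is None else genotypes[i]
        fv = {k: (v[i] if isinstance(v, (list, tuple, np.ndarray)) else v)
              for k, v in factors.items()}
        cs.add(make_variant(pos, genotype=gt, chrom=chrom, **fv))
    return cs


def make_consensus(calls, chrom="chr1", ref="A", coverage=50.0):
    """Consensus frame from {pos: call_symbol}; constant ref/coverage
    unless dicts are given."""
    rows = []
    for pos, call in calls.items():
        rows.append({
            "chrom": chrom, "pos": pos,
            "ref": ref[pos] if isinstance(ref, dict) else ref,
            "call": call,
            "coverage": coverage[pos] if isinstance(coverage, dict) else coverage,
            "vac": np.nan, "vaf": np.nan, "vaq": np.nan, "pvalue": np.nan,
        })
    return pd.DataFrame(rows).set_index(["chrom", "pos"]).sort_index()


@pytest.fixture(scope="session")
def sim_pair():
    """One simulated duplicate pair under the default study conditions."""
    reps, truth, gc = simulate_replicate_set(SimulationConfig(seed=11))
    return reps, truth, gc


@pytest.fixture(scope="session")
def sim_status_table(sim_pair):
    from varconcord.association import pool_status
    reps, _, _ = sim_pair
    return pool_status(reps.pairs())
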