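"""Shared fixtures: small toy objects plus one default-scale simulation."""

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest

import capture3c as c3


@pytest.fixture(scope="session")
def toy_fragment_map() -> c3.FragmentMap:
    """21-bp chromosome with two HindIII sites -> fragments 3/10/8 bp."""
    return c3.digest_genome({"chrT": "GGGAAGCTTCCCCAAGCTTTT"}, "AAGCTT")


@pytest.fixture(scope="session")
def default_sim():
    """Default-scale simulated experiment shared by the slower tests.

    Two 5-Mb chromosomes digested with HindIII, viewpoint at the chr1
    midpoint.  The genome and fragment map are simulated once; tests draw
    reads with their own seeds via ``replace(cfg, seed=...)``.
    """
    cfg = c3.SimulationConfig(seed=11)
    genome = c3.simulate_genome(cfg)
    fm = c3.digest_genome(genome, cfg.enzyme_site)
    vp = cfg.resolve_viewpoint(fm)
    return cfg, fm, vp


def run_pipeline(cfg, fm, vp, informative_only=False):
    """Simulate reads and run count -> normalize -> call; returns the calls."""
    reads, _ = c3.simulate_3cseq(cfg, fm)
    counts = c3.count_per_fragment(reads, fm, informative_only=informative_only)
    signals = c3.simple_rpm(counts)
    fit = c3.fit_powerlaw(signals, viewpoint=vp)
    signals = c3.powerlaw_normalize(signals, fit)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return c3.call_interactions(signals, vp)


@pytest.fixture(scope="session")
def spiked_calls(default_sim):
    """Two replicate call sets from the same 20-spike configuration."""
    cfg, fm, vp = default_sim
    rng = np.random.default_rng(2025)
    spike_ids = c3.choose_spike_fragments(fm, vp, 20, rng)
    spiked = dataclasses.replace(
        cfg, spikes=tuple((int(i), 10.0) for i in spike_ids)
    )
    rep1 = run_pipeline(dataclasses.replace(spiked, seed=21), fm, vp)
    rep2 = run_pipeline(dataclasses.replace(spiked, seed=22), fm, vp)
    return spike_ids, rep1, rep2
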