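"""Shared fixtures: small deterministic cohorts and helpers."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from invstruct import SimConfig, draw_cohort
from invstruct.core import Interval
from invstruct.simulate import RecombTract


@pytest.fixture(scope="session")
def two_hap_config() -> SimConfig:
    """Balanced H1.β1 / H2.α1 cohort: every genotype group populated."""
    return SimConfig(
        n_individuals=120,
        haplotype_freqs={"H1.β1": 0.5, "H2.α1": 0.5},
        snp_density=2.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def four_hap_config() -> SimConfig:
    return SimConfig(n_individuals=150, seed=7)


def cohort_with_tracts(
    base: SimConfig,
    tract_spans: list[tuple[int, int]],
    donor: str = "H1",
    carrier_genotype: str = "H1/H2",
):
    """Re-draw ``base`` with tracts implanted into distinct eligible
    individuals (the draw is unchanged by tract configuration)."""
    truth0 = draw_cohort(base)
    eligible = [
        i for i in range(base.n_individuals)
        if truth0.inversion_genotype(i) == carrier_genotype
    ]
    if len(eligible) < len(tract_spans):
        raise RuntimeError("not enough eligible individuals for requested tracts")
    tracts = tuple(
        RecombTract(ind, Interval(base.locus.contig, s, e), donor)
        for ind, (s, e) in zip(eligible, tract_spans)
    )
    cfg = dataclasses.replace(base, recomb_tracts=tracts)
    return draw_cohort(cfg), cfg, tracts
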