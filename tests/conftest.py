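import logging

import numpy as np
import pandas as pd
import pytest

import prepvote as pv

logging.getLogger("prepvote").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cohort() -> pv.LatentCohort:
    """200 patients x 100 genes, 20 signature genes, 3 datasets."""
    return pv.generate_latent_cohort(
        n_patients=200,
        n_genes=100,
        n_signature_genes=20,
        n_datasets=3,
        loading_strength=1.5,
        seed=11,
        baseline_rate=0.08,
        censoring_rate=0.05,
    )


@pytest.fixture(scope="session")
def small_variants(small_cohort):
    specs = pv.enumerate_pipelines()
    distortions = pv.default_distortion_specs(specs, noise_sd=0.5, batch_sd=0.5, seed=12)
    return pv.apply_pipeline_variants(small_cohort, distortions, seed=13)


@pytest.fixture(scope="session")
def small_votes(small_cohort, small_variants):
    signature = pv.GeneSignature("true", small_cohort.signature_genes)
    return pv.score_all_pipelines(small_variants, signature, small_cohort.survival)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def _finite_cox_mle(times, events, groups):
    """True when the binary-covariate partial likelihood has a finite maximizer.

    Checked from first principles: the concave log partial likelihood has a
    finite maximum iff its slope is positive as beta -> -inf and negative as
    beta -> +inf.
    """
    d1_sum = lo_sum = hi_sum = 0
    for t in sorted(set(times[events == 1])):
        at = times >= t
        n1 = int((at & (groups == 1)).sum())
        n0 = int((at & (groups == 0)).sum())
        d = int(((times == t) & (events == 1)).sum())
        d1_sum += int(((times == t) & (events == 1) & (groups == 1)).sum())
        if n0 == 0:
            lo_sum += d
        if n1 > 0:
            hi_sum += d
    return d1_sum > lo_sum and d1_sum < hi_sum


def random_survival(rng, n, p_event=0.7):
    """Small random survival data with both groups present and a finite Cox MLE."""
    while True:
        times = rng.uniform(0.5, 10.0, size=n)
        events = (rng.random(n) < p_event).astype(int)
        groups = rng.integers(0, 2, size=n)
        if groups.min() == 0 and groups.max() == 1 and _finite_cox_mle(times, events, groups):
            return times, events, groups
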