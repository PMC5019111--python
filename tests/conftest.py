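"""Shared fixtures: one synthetic dataset + trained models per session."""

import math

import numpy as np
import pytest

from splicevar import synthetic_fixtures as sf
from splicevar.site_models import PositionalMarkovModel, train_site_model


@pytest.fixture(scope="session")
def spec():
    return sf.FixtureSpec(seed=1)


@pytest.fixture(scope="session")
def fixture(spec):
    return sf.build_fixture(spec)


@pytest.fixture(scope="session")
def trained_models(spec, fixture):
    donor = train_site_model(
        fixture.training_windows["donor"], fixture.background, "donor"
    )
    acceptor = train_site_model(
        fixture.training_windows["acceptor"], fixture.background, "acceptor"
    )
    return {"donor": donor, "acceptor": acceptor}


@pytest.fixture()
def toy_model():
    """3-position order-2 model with hand-assigned conditional tables."""
    m = PositionalMarkovModel(site_kind="donor", window_length=3, order=2)
    probs = {
        # position 0: order-0
        (0, "", "G"): 0.5, (0, "", "A"): 0.3, (0, "", "C"): 0.1, (0, "", "T"): 0.1,
        # position 1: order-1, context G and A
        (1, "G", "T"): 0.7, (1, "G", "A"): 0.1, (1, "G", "C"): 0.1, (1, "G", "G"): 0.1,
        (1, "A", "T"): 0.25, (1, "A", "A"): 0.25, (1, "A", "C"): 0.25, (1, "A", "G"): 0.25,
        # position 2: order-2, contexts GT and AT
        (2, "GT", "A"): 0.6, (2, "GT", "C"): 0.2, (2, "GT", "G"): 0.1, (2, "GT", "T"): 0.1,
        (2, "AT", "A"): 0.4, (2, "AT", "C"): 0.3, (2, "AT", "G"): 0.2, (2, "AT", "T"): 0.1,
    }
    bg = {
        ("", "A"): 0.25, ("", "C"): 0.25, ("", "G"): 0.3, ("", "T"): 0.2,
        ("G", "T"): 0.3, ("G", "A"): 0.3, ("G", "C"): 0.2, ("G", "G"): 0.2,
        ("A", "T"): 0.2, ("A", "A"): 0.4, ("A", "C"): 0.2, ("A", "G"): 0.2,
        ("GT", "A"): 0.25, ("GT", "C"): 0.25, ("GT", "G"): 0.25, ("GT", "T"): 0.25,
        ("AT", "A"): 0.3, ("AT", "C"): 0.3, ("AT", "G"): 0.2, ("AT", "T"): 0.2,
    }
    for key, p in probs.items():
        m.site_logprob[key] = math.log(p)
        m.seen_contexts.add(key)
    for (ctx, b), p in bg.items():
        m.background_logprob[(len(ctx), ctx, b)] = math.log(p)
    m.toy_site_probs = probs
    m.toy_bg_probs = bg
    return m
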