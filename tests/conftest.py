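"""Shared fixtures: forward-model feature tables, corpora, exact models."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import fermsense as fs

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def forward_feature_table(probe: fs.ProbeModel, od, af_pct=None,
                          gamma=None) -> pd.DataFrame:
    """Exact (noise-free, lag-free) feature/target rows from the optical
    forward model at given true ODs and antifoam %vol levels.

    This is the algebraic ground truth the calibration should recover
    perfectly: 1/T = (1 + k_t (OD + gamma AF%)) / c_t and
    R = r0 + r1 OD + r2 AF%.
    """
    od = np.asarray(od, dtype=float)
    af = np.zeros_like(od) if af_pct is None else np.asarray(af_pct, dtype=float)
    g = probe.gamma_t if gamma is None else gamma
    inv_trans = (1.0 + probe.k_t * (od + g * af)) / probe.c_t
    refl = probe.r0 + probe.r1 * od + probe.r2 * af
    return pd.DataFrame({
        "inv_trans_ma": inv_trans,
        "refl_ma": refl,
        "antifoam_pct": af,
        "interaction": inv_trans * refl,
        "offline_od": od,
    })


@pytest.fixture(scope="session")
def default_probe():
    return fs.ProbeModel()


@pytest.fixture(scope="session")
def plateau_table(default_probe):
    """Constant-OD plateaus over the full dynamic range 0-140 with
    independently varied antifoam, exactly linear in the model features."""
    od = np.arange(0.0, 150.0, 10.0)
    af = np.tile([0.0, 0.3, 0.6], 5)
    return forward_feature_table(default_probe, od, af)


@pytest.fixture(scope="session")
def exact_model(plateau_table):
    """OLS calibration fitted on noiseless plateau data: reproduces the
    forward model to machine precision.

    On noiseless plateaus the full four-term predictor set is exactly
    collinear (inverse transmission, reflection and antifoam %vol are all
    affine in the two underlying factors OD and AF%), so the exact fit
    uses the minimal identifiable pair — the redundancy is only broken by
    measurement noise on real/noisy data.
    """
    return fs.InlineODModel(
        plateau_table, feature_names=("inv_trans_ma", "refl_ma")
    ).fit(method="olsr", seed=0)


@pytest.fixture(scope="session")
def corpus_seed1():
    """Campaign-scale synthetic calibration campaign (15 runs, 159 offline
    points, 5 probes), one fixed seed."""
    corpus, runs = fs.generate_training_corpus(
        n_runs=15, n_offline_total=159, n_probes=5, seed=1)
    return corpus, runs


@pytest.fixture(scope="session")
def small_corpus():
    """A small, fast corpus for IO/transfer/CLI tests."""
    corpus, runs = fs.generate_training_corpus(
        n_runs=4, n_offline_total=48, n_probes=2, seed=11)
    return corpus, runs


@pytest.fixture(scope="session")
def olsr_seed1(corpus_seed1):
    corpus, _ = corpus_seed1
    return fs.InlineODModel(corpus).fit(method="olsr", seed=1)
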