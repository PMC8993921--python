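import numpy as np
import pytest

from famgeo import experiments as ex
from famgeo._nn import MLP
from famgeo.alphabet import Alphabet, PROTEIN
from famgeo.vae import EntropyNetParams, TrainingConfig, VaeModel, fit_vae


def constant_model(probs, alphabet=None, entropy=None):
    """VaeModel whose decoder outputs the given (L, C) distribution at every
    latent point: zero-weight bias-only decoder.  Useful as an analytically
    tractable toy."""
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    L, C = probs.shape
    if alphabet is None:
        if C == PROTEIN.C:
            alphabet = PROTEIN
        else:
            alphabet = Alphabet(symbols="ACDEFGHIKLMNPQRSTVWY-"[:C - 1] + "-", gap="-")
    assert alphabet.C == C
    rng = np.random.default_rng(0)
    enc = MLP([L * C, 4, 4], rng)
    dec = MLP([2, L * C], rng)
    dec.params[0][:] = 0.0
    dec.params[1][:] = np.log(np.maximum(probs, 1e-12)).ravel()
    return VaeModel(enc, dec, alphabet, L, 2, entropy=entropy, seed=0)


def linear_logit_model(W, L, C, entropy=None):
    """Decoder with logits = z @ W (single linear layer); analytic toy."""
    alphabet = Alphabet(symbols="ACDEFGHIKLMNPQRSTVWY-"[:C - 1] + "-", gap="-")
    rng = np.random.default_rng(0)
    enc = MLP([L * C, 4, 4], rng)
    dec = MLP([2, L * C], rng)
    dec.params[0][:] = np.asarray(W, dtype=float)
    dec.params[1][:] = 0.0
    return VaeModel(enc, dec, alphabet, L, 2, entropy=entropy, seed=0)


def far_entropy_params(beta=1.0):
    """Entropy network with a single center at the origin."""
    return EntropyNetParams(np.zeros((1, 2)), float(np.log(np.expm1(beta))))


@pytest.fixture(scope="session")
def tiny_sim():
    import famgeo

    tree = famgeo.simulate_tree(40, seed=1)
    return famgeo.evolve_family(tree, 30, rate=1.0, seed=1)


@pytest.fixture(scope="session")
def tiny_model(tiny_sim):
    cfg = TrainingConfig(phase1_epochs=100, phase2_epochs=60, K=10)
    return fit_vae(tiny_sim.family, None, cfg, seed=0)


@pytest.fixture(scope="session")
def default_sim():
    return ex.default_family(seed=0)


@pytest.fixture(scope="session")
def default_model(default_sim):
    return ex.train_default(default_sim, seed=0)


@pytest.fixture(scope="session")
def ensemble_models(default_sim, default_model):
    others = [ex.train_default(default_sim, seed=s) for s in (1, 2, 3, 4)]
    return [default_model] + others
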