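import numpy as np
import pytest

from crloc import _nn
from crloc.crnet import ModelConfig, build_model, stage_sampler
from crloc.synthcr import BackgroundSpec, CRSpec, NoiseSpec, make_patch


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# tiny training problems: small patches with uniform dark background, used
# to exercise the training loops quickly (the canonical 180-px generators
# are exercised in the acceptance tests)


def tiny_sampler(stage: int, size: int = 24):
    def sample_fn(n, rng):
        images = np.empty((n, size, size), dtype=np.float32)
        targets = np.empty((n, 2), dtype=np.float32)
        for i in range(n):
            r = rng.uniform(2.0, 4.0)
            A = rng.uniform(5.0, 100.0)
            if stage == 1:
                x_c = rng.uniform(r, size - r)
                y_c = rng.uniform(r, size - r)
            else:
                x_c = size / 2.0 + rng.uniform(-0.75, 0.75)
                y_c = size / 2.0 + rng.uniform(-0.75, 0.75)
            patch = make_patch(
                CRSpec(x_c=x_c, y_c=y_c, r=r, A=A),
                BackgroundSpec(dark_level=10.0, light_level=None),
                NoiseSpec(sigma_n=rng.uniform(0.0, 5.0), seed=int(rng.integers(2**31))),
                size=size,
            )
            images[i] = patch.pixels
            targets[i] = (x_c, y_c)
        return images, targets

    return sample_fn


TINY_CFG = ModelConfig(
    input_size=24,
    conv_filters=(4, 4, 8),
    dense_widths=(8, 2),
    batch_size=4,
    epoch_size=16,
    n_val=12,
    max_epochs=2,
    patience=5,
)


@pytest.fixture
def tiny_cfg():
    return TINY_CFG


# ---------------------------------------------------------------------------
# shared desk-scale CNN: reduced filter counts at the full 180-px input,
# trained briefly on near-centered synthetic patches with the circular
# 48-px inference mask applied, so it is usable on eye-pipeline cutouts


SMALL_CFG = ModelConfig(
    conv_filters=(8, 8, 16, 16, 32, 32, 64), dense_widths=(32, 2), batch_size=8
)


def masked_stage2_sampler():
    y, x = np.mgrid[0:180, 0:180]
    outside = (x - 90) ** 2 + (y - 90) ** 2 > 48.0**2
    base = stage_sampler(2)

    def sample_fn(n, rng):
        images, targets = base(n, rng)
        images[:, outside] = 0.0
        return images, targets

    return sample_fn


@pytest.fixture(scope="session")
def small_model():
    """Briefly trained small CNN shared across tests (built once)."""
    model = build_model(SMALL_CFG, seed=0)
    sample_fn = masked_stage2_sampler()
    train_rng = np.random.default_rng(7)
    opt = _nn.Adam(lr=1e-3)
    for _ in range(300):
        x, y = sample_fn(SMALL_CFG.batch_size, train_rng)
        model.train_step(x, y, opt)
    return model
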