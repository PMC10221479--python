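import numpy as np
import pytest
from hypothesis import settings

import footarch as fa

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def palette():
    return fa.default_palette()


@pytest.fixture
def rng():
    return np.random.default_rng(20230426)


@pytest.fixture
def render(tmp_path):
    """Render a FootSpec (or a ready image array) to a PNG and return its path."""

    counter = {"n": 0}

    def _render(spec_or_image):
        counter["n"] += 1
        path = tmp_path / f"fixture_{counter['n']}.png"
        if isinstance(spec_or_image, fa.FootSpec):
            image, _ = fa.generate(spec_or_image)
        else:
            image = spec_or_image
        fa.save_image(image, path)
        return path

    return _render


def random_blob(rng, shape=(40, 40), n_seeds=4, dilations=3):
    """A random connected-ish binary blob for brute-force oracle tests."""
    from scipy import ndimage

    mask = np.zeros(shape, dtype=bool)
    ys = rng.integers(5, shape[0] - 5, size=n_seeds)
    xs = rng.integers(5, shape[1] - 5, size=n_seeds)
    mask[ys, xs] = True
    mask = ndimage.binary_dilation(mask, iterations=dilations)
    return mask


def crop_from_labels(labels, side=fa.FootSide.RIGHT):
    """Wrap a class-label array as a FootCrop with a rendered color image."""
    labels = np.asarray(labels, dtype=np.uint8)
    return fa.FootCrop(
        image=fa.render_class_map(labels),
        class_map=labels,
        offset=(0, 0),
        side=side,
    )
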