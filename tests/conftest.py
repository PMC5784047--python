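"""Shared fixtures: small seeded stimulus sets and a compact network."""

import numpy as np
import pytest

from numerosense import network, stimuli


@pytest.fixture(scope="session")
def bank():
    return network.build_filterbank()


@pytest.fixture(scope="session")
def image_fixture_500():
    """500 generated images spanning numerosities and area regimes."""
    rng = np.random.default_rng(1234)
    images = []
    for i in range(500):
        n = int(rng.integers(1, 33))
        if rng.random() < 0.5:
            area = "free"
        else:
            area = int(rng.choice([a for a in stimuli.AREA_LEVELS if a >= n]))
        images.append(stimuli.generate_image(n, area_target=area, rng=rng,
                                             seed_tag=f"fix:{i}"))
    return images


@pytest.fixture(scope="session")
def small_layer(bank):
    return network.GenerativeLayer.initialize(
        bank.n_features, 50, rng=np.random.default_rng(7))


@pytest.fixture(scope="session")
def easy_pairs():
    """Large-ratio comparison pairs (easy discriminations)."""
    rng = np.random.default_rng(11)
    return stimuli.generate_comparison_pairs(
        ratios=[(1, 4), (1, 6)], count_per_ratio=40,
        congruency="uncontrolled", rng=rng)


def brute_force_components(pixels):
    """Independent 4-connectivity component count (BFS oracle)."""
    pix = (np.asarray(pixels) != 0)
    seen = np.zeros_like(pix, dtype=bool)
    h, w = pix.shape
    count = 0
    for r in range(h):
        for c in range(w):
            if pix[r, c] and not seen[r, c]:
                count += 1
                stack = [(r, c)]
                seen[r, c] = True
                while stack:
                    y, x = stack.pop()
                    for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and pix[ny, nx] \
                                and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
    return count


def brute_force_contour(pixels):
    pix = (np.asarray(pixels) != 0)
    h, w = pix.shape
    total = 0
    for r in range(h):
        for c in range(w):
            if not pix[r, c]:
                continue
            for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ny, nx = r + dy, c + dx
                if not (0 <= ny < h and 0 <= nx < w) or not pix[ny, nx]:
                    total += 1
                    break
    return total
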