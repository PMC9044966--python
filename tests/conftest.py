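"""Shared fixtures: small synthetic scenes rendered once per session."""

import numpy as np
import pytest

import tomatophen as tp
from tomatophen import synthetic as syn


@pytest.fixture(scope="session")
def pure_preset():
    return tp.builtin_presets()["pure_color"]


@pytest.fixture(scope="session")
def scale50():
    return tp.PixelScale(50.0)


@pytest.fixture(scope="session")
def intact_scene():
    spec = syn.make_intact_scene(3, seed=11, speckle=0)
    img, records, _ = syn.render_scene(spec, seed=11)
    return spec, img, records


@pytest.fixture(scope="session")
def vertical_scene():
    spec = syn.make_vertical_scene(3, seed=7)
    img, records, _ = syn.render_scene(spec, seed=7)
    return spec, img, records


@pytest.fixture(scope="session")
def horizontal_scene():
    spec = syn.make_horizontal_scene(3, seed=5)
    img, records, ann = syn.render_scene(spec, seed=5)
    return spec, img, records, ann


@pytest.fixture(scope="session")
def ruler_image():
    img, record = syn.render_ruler_card(40.0, (400, 400))
    return img, record
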