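import numpy as np
import pytest

from smstoich.camera import TIRF_EMCCD
from smstoich.synth import SceneConfig, generate_scene, render_movie


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def single_emitter_factory():
    """Render a lone immobile n-mer in a small field; returns (stack, scene)."""

    def make(k=1, seed=7, n_frames=1, noise=False, background_photons=0.0,
             brightness_cv=0.0, photons_per_fluorophore=250.0):
        cfg = SceneConfig(
            field_size_nm=(6400.0, 6400.0),
            n_emitters=1,
            order_distribution={k: 1.0},
            labeling_p=1.0,
            min_separation_nm=0.0,
            border_nm=2500.0,
        )
        scene = generate_scene(cfg, seed=seed)
        stack, truth = render_movie(
            scene,
            camera=TIRF_EMCCD,
            photons_per_fluorophore=photons_per_fluorophore,
            n_frames=n_frames,
            seed=seed + 1,
            background_photons=background_photons,
            brightness_cv=brightness_cv,
            noise=noise,
        )
        return stack, scene

    return make
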