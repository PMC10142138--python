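import pytest

from tumorcontrast import PhantomSpec, builtin_effects, render_phantom


@pytest.fixture(scope="session")
def small_spec():
    """A small noiseless phantom — fast to render, same means as any size."""
    from tumorcontrast import Ellipse
    return PhantomSpec(
        grid_width=64, grid_height=64,
        tissue_ellipse=Ellipse(32, 32, 25, 15),
        tumor_ellipse=Ellipse(32, 32, 8, 5),
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return render_phantom(small_spec)


@pytest.fixture(scope="session")
def agents():
    return {e.name: e for e in builtin_effects()}
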