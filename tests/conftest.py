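import pytest
from hypothesis import settings

from trimsight import (
    ProfileSpec,
    RenderStyle,
    parse_fastqc_html,
    render_plot,
    simulate_profile,
    wrap_html,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


#: Noiseless spec with a closed-form Q20 lower-quartile crossing at base 229.
NOISELESS_SPEC = ProfileSpec(
    read_length=250, plateau_q=38.0, decay_start=200, decay_rate=0.5,
    noise_sd=0.0, iqr_half_width=4.0, seed=1,
)


@pytest.fixture(scope="session")
def noiseless_profile():
    return simulate_profile(NOISELESS_SPEC)


@pytest.fixture(scope="session")
def rendered(noiseless_profile):
    """(image, sidecar) of the canonical noiseless fixture."""
    return render_plot(noiseless_profile, RenderStyle())


@pytest.fixture(scope="session")
def fixture_report(rendered, tmp_path_factory):
    """A QCReport round-tripped through the HTML shell."""
    image, _ = rendered
    path = tmp_path_factory.mktemp("html") / "report.html"
    path.write_text(wrap_html(image, 250, "fixture_R1.fastq"), encoding="utf-8")
    return parse_fastqc_html(path)
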