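import pytest
from hypothesis import HealthCheck, settings

import sigmaqe as sq

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=200,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def paper_flash():
    """The instrument flash: 80 us, 1 W/cm^2 peak, 450 nm blue LEDs."""
    return sq.FlashSpec(
        wavelength_nm=450.0, duration_us=80.0, peak_power_w_cm2=1.0
    )


@pytest.fixture(scope="session")
def protocol():
    return sq.default_protocol()


def make_panel_curves(noise, seed, n_replicates=5, **strain_overrides):
    """LL+HL default-panel curves with optional strain-field overrides."""
    from dataclasses import replace

    curves = []
    for acclim in ("LL", "HL"):
        for strain in sq.default_panel(acclim):
            if strain_overrides:
                strain = replace(strain, **strain_overrides)
            for rep in range(n_replicates):
                curves.append(
                    sq.simulate_light_curve(
                        strain,
                        sq.default_protocol(),
                        noise_rel_sd=noise,
                        seed=seed,
                        replicate_index=rep,
                        acclimation=acclim,
                    )
                )
    return curves
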