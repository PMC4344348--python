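import pytest

from bindscreen import afmforce, sprkinetics, synthdata


@pytest.fixture
def egf_like_params() -> sprkinetics.KineticParameters:
    """Kinetics landing on the natural-ligand K_D magnitude (1.77e-7 M)."""
    return sprkinetics.KineticParameters(ka=1e5, kd=1.77e-2, rmax=100.0)


@pytest.fixture
def protocol() -> synthdata.InjectionProtocol:
    """30 s baseline, 300 s association, 300 s dissociation at 1 Hz."""
    return synthdata.InjectionProtocol(
        t_assoc_start=30.0, t_assoc_end=330.0, t_diss_end=630.0, sampling_interval=1.0
    )


@pytest.fixture
def noiseless(egf_like_params, protocol) -> synthdata.SensorgramSeries:
    noise = synthdata.SensorgramNoiseModel(sigma_ru=0.0, seed=0)
    return synthdata.simulate_sensorgram_series(egf_like_params, protocol, noise)


@pytest.fixture
def cantilever() -> afmforce.CantileverSpec:
    return afmforce.CantileverSpec(spring_constant=0.105)


@pytest.fixture
def adhesion_truth() -> synthdata.AdhesionGroundTruth:
    return synthdata.AdhesionGroundTruth(
        mu_f=210.0, sigma_f=30.0, frac_zero=0.2, frac_nonspecific=0.1, n_curves=200
    )
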